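import numpy as np
import pytest

from invscout.model import InsertProfile, Interval
from invscout.synthetic_data import (
    apply_inversion,
    generate_genome,
    plant_inverted_lcr,
)


@pytest.fixture(scope="session")
def small_genome():
    """10 kb random genome, balanced GC."""
    return generate_genome(10_000, 0.5, seed=11)


@pytest.fixture(scope="session")
def inverted_scenario():
    """100 kb genome with one planted inversion [30000, 70000) and its donor."""
    ref = generate_genome(100_000, 0.45, seed=21)
    donor = apply_inversion(ref, 30_000, 70_000)
    return ref, donor


@pytest.fixture(scope="session")
def lcr_genome():
    """200 kb genome with a planted 5 kb inverted LCR pair at 98% identity."""
    g = generate_genome(200_000, 0.42, seed=31)
    return plant_inverted_lcr(g, 5_000, 80_000, identity_pct=98.0,
                              anchor_bp=50_000, seed=32)


@pytest.fixture
def profile():
    return InsertProfile(mean_bp=350.0, sd_bp=35.0, read_len_bp=100)
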