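"""Published reference inputs bundled with the package.

The cohort variant table lists the rare protein-coding DPP6 variants
reported in Belgian early-onset Alzheimer and frontotemporal dementia
patient cohorts; it drives the consequence-classification worked example.
The long-read breakpoint coordinates are the hg19 positions at which the
index family's chromosome-7 inversion was independently mapped by a
nanopore strand-flip caller.
"""
from __future__ import annotations

from importlib import resources as _ilres

import pandas as pd

#: hg19 coordinates of the index inversion mapped by long-read sequencing
LONG_READ_PROXIMAL_BP = 149_704_610
LONG_READ_DISTAL_BP = 153_786_893


def load_cohort_variant_table() -> pd.DataFrame:
    """The patient-only rare DPP6 coding variants (one row per carrier)."""
    with _ilres.files("invscout.data").joinpath("dpp6_cohort_variants.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"aao": "Int64", "aai": "Int64"})


def inversion_span_mb(proximal_bp: int, distal_bp: int) -> int:
    """Inversion size implied by two breakpoints, rounded to the nearest Mb."""
    return round((distal_bp - proximal_bp) / 1_000_000)
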