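"""Association statistics against independent oracles."""
from fractions import Fraction
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from invscout.assoc_stats import (
    chi_square_test,
    classify_consequence,
    fisher_allelic,
    geometric_normalize,
    mann_whitney_exact,
    permutation_burden,
)
from invscout.model import ValidationError
from invscout.resources import load_cohort_variant_table


class TestClassifyConsequence:
    @pytest.mark.parametrize("token,expected", [
        ("p.Q230*", "PTC"),
        ("p.E79Gfs*9", "PTC"),
        ("p.G61_G62dup", "inframe_indel"),
        ("p.A5D", "missense"),
        ("p.R47L", "missense"),
        ("p.K128=", "synonymous"),
        ("p.Gln230Ter", "PTC"),
        ("p.Ala5Asp", "missense"),
        ("p.G61del", "inframe_indel"),
    ])
    def test_grammar(self, token, expected):
        assert classify_consequence(token) == expected

    def test_unparseable_warns_and_is_other(self):
        with pytest.warns(UserWarning):
            assert classify_consequence("p.???") == "other"
        with pytest.warns(UserWarning):
            assert classify_consequence("c.688C>T") == "other"

    def test_cohort_table_parses_without_other(self):
        table = load_cohort_variant_table()
        classes = table["protein"].map(classify_consequence)
        assert "other" not in set(classes)


def _fisher_oracle(a, r1, c, r2):
    """Exact rational two-sided p by enumerating tables with fixed margins."""
    c1 = a + c
    n = r1 + r2
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        k: Fraction(
            factorial(r1) * factorial(r2) * factorial(c1) * factorial(n - c1),
            factorial(n) * factorial(k) * factorial(r1 - k)
            * factorial(c1 - k) * factorial(r2 - c1 + k),
        )
        for k in range(k_lo, k_hi + 1)
    }
    return float(sum(v for v in probs.values() if v <= probs[a]))


class TestFisherAllelic:
    def test_symmetric_table(self):
        res = fisher_allelic(5, 200, 5, 200)
        assert res.odds_ratio == 1.0 and res.p_two_sided == 1.0
        assert res.ci95[0] <= 1.0 <= res.ci95[1]

    def test_small_table_matches_enumeration(self):
        res = fisher_allelic(3, 8, 1, 8)
        assert res.p_two_sided == pytest.approx(_fisher_oracle(3, 8, 1, 8),
                                                abs=1e-14)

    def test_zero_cell_gets_finite_or(self):
        res = fisher_allelic(0, 100, 5, 100)
        assert 0 < res.odds_ratio < 1
        assert np.isfinite(res.ci95).all()
        assert res.p_two_sided == pytest.approx(_fisher_oracle(0, 100, 5, 100),
                                                abs=1e-12)

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(151)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            res = fisher_allelic(a, a + b, c, c + d)
            table = [[a, b], [c, d]]
            assert res.p_two_sided == pytest.approx(
                stats.fisher_exact(table).pvalue, rel=1e-7, abs=1e-12
            )

    def test_negative_counts_raise(self):
        with pytest.raises(ValidationError):
            fisher_allelic(5, 3, 0, 10)


def _mwu_oracle(xs, ys):
    """Independent enumeration: U from pairwise comparisons per labeling."""
    pool = list(xs) + list(ys)
    n = len(xs)
    def u_of(group_a, group_b):
        return sum((a > b) + 0.5 * (a == b) for a in group_a for b in group_b)
    centre = n * len(ys) / 2
    obs = abs(u_of(xs, ys) - centre)
    hits = total = 0
    for idx in combinations(range(len(pool)), n):
        ga = [pool[i] for i in idx]
        gb = [pool[i] for i in range(len(pool)) if i not in idx]
        total += 1
        if abs(u_of(ga, gb) - centre) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_tiny_exact_example(self):
        u, p = mann_whitney_exact([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_give_p_one(self):
        _, p = mann_whitney_exact([1.0, 2.0, 5.0], [5.0, 1.0, 2.0])
        assert p == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xs = rng.normal(size=6).round(1)
        ys = rng.normal(0.5, size=6).round(1)
        _, p = mann_whitney_exact(xs, ys)
        assert p == pytest.approx(_mwu_oracle(xs, ys), abs=1e-12)

    def test_label_symmetry(self):
        xs, ys = [1.0, 4.0, 6.0], [2.0, 3.0, 8.0, 9.0]
        u_a, p_a = mann_whitney_exact(xs, ys)
        u_b, p_b = mann_whitney_exact(ys, xs)
        assert u_a + u_b == len(xs) * len(ys)
        assert p_a == p_b

    def test_empty_group_raises(self):
        with pytest.raises(ValidationError):
            mann_whitney_exact([], [1.0])


class TestChiSquare:
    def test_homogeneous_table(self):
        stat, p, dof = chi_square_test([[10, 10], [10, 10]])
        assert stat == 0 and p == 1 and dof == 1

    def test_hand_computed_statistic(self):
        stat, _, _ = chi_square_test([[20, 10], [10, 20]])
        assert stat == pytest.approx(20 / 3)

    def test_rxc_degrees_of_freedom(self):
        _, _, dof = chi_square_test([[5, 6, 7], [8, 9, 10]])
        assert dof == 2

    def test_zero_expected_raises(self):
        with pytest.raises(ValidationError):
            chi_square_test([[0, 0], [5, 5]])


class TestGeometricNormalize:
    def test_exact_powers(self):
        df = pd.DataFrame({"target": [8.0], "ref1": [2.0], "ref2": [32.0]})
        out = geometric_normalize(df, ["ref1", "ref2"])
        assert out.loc[0, "target"] == pytest.approx(1.0)

    def test_equal_references_reduce_to_division(self):
        df = pd.DataFrame({"target": [6.0, 9.0], "r1": [3.0, 3.0],
                           "r2": [3.0, 3.0]})
        out = geometric_normalize(df, ["r1", "r2"])
        assert out["target"].tolist() == pytest.approx([2.0, 3.0])

    def test_per_sample_scale_invariance(self):
        df = pd.DataFrame({"t": [5.0, 7.0], "r1": [2.0, 3.0], "r2": [4.0, 5.0]})
        scaled = df.copy()
        scaled.iloc[1] *= 10
        a = geometric_normalize(df, ["r1", "r2"])
        b = geometric_normalize(scaled, ["r1", "r2"])
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_reference_raises(self):
        df = pd.DataFrame({"t": [1.0], "r1": [0.0]})
        with pytest.raises(ValidationError):
            geometric_normalize(df, ["r1"])


class TestPermutationBurden:
    def test_constant_phenotype_raises(self):
        G = np.zeros((10, 3))
        with pytest.raises(ValidationError):
            permutation_burden(G, np.ones(10), n_perm=1000, seed=1)

    def test_too_few_permutations_raise(self):
        rng = np.random.default_rng(3)
        G = rng.binomial(2, 0.005, size=(50, 5))
        y = np.r_[np.ones(25), np.zeros(25)]
        with pytest.raises(ValidationError):
            permutation_burden(G, y, n_perm=10, seed=1)

    def test_single_variant_agrees_with_hypergeometric_carrier_test(self):
        # with one 0/1 variant the permutation null of the carrier-in-case
        # count K is Hypergeom(n, C, n/2) and the omnibus statistic is
        # monotone in (K - C/2)^2, so the expected (randomized-tie) p equals
        # the hypergeometric mid-p of the deviation ordering
        n, C = 2000, 12
        g = np.zeros(n, dtype=int)
        g[:8] = 1   # 8 carriers among cases
        g[n // 2 : n // 2 + C - 8] = 1  # 4 among controls
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        ps = [
            permutation_burden(g[:, None], y, n_perm=4000, seed=s).p_value
            for s in range(30)
        ]
        k = int(g[y == 1].sum())
        support = np.arange(0, C + 1)
        pmf = stats.hypergeom.pmf(support, n, C, n // 2)
        dev = np.abs(support - C / 2)
        obs_dev = abs(k - C / 2)
        mid_p = pmf[dev > obs_dev].sum() + 0.5 * pmf[dev == obs_dev].sum()
        assert abs(np.mean(ps) - mid_p) < 0.05

    def test_detects_strong_burden(self):
        rng = np.random.default_rng(167)
        n, m = 2000, 20
        G = rng.binomial(2, 0.002, size=(n, m))
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        # case-only enrichment that keeps every variant under the 1% MAF gate
        G[: n // 2, :8] |= rng.binomial(1, 0.008, size=(n // 2, 8))
        res = permutation_burden(G, y, n_perm=2000, seed=11)
        assert res.p_value < 0.01
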