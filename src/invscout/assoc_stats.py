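"""Association statistics for rare-variant analyses.

Contents: allelic Fisher exact test with odds ratio and Woolf 95% CI,
a permutation-calibrated rare-variant burden/variance-component omnibus
test (the SKAT-O statistic family with Beta(1,25) MAF weights, with exact
analytic p-values replaced by phenotype-label permutation), exact
Mann–Whitney U for small samples, Pearson chi-square for familial-load
enrichment, HGVS-protein consequence classification, and multi-reference-gene
geometric-mean expression normalization (the geNorm convention).
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb, exp, log, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .model import ValidationError

# ---------------------------------------------------------------------------
# consequence classification

AA1 = "ARNDCQEGHILKMFPSTWYV"
AA3 = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr|Trp|"
    "Tyr|Val|Ter"
)
_AA3_TO_1 = dict(zip(AA3.split("|"), list(AA1) + ["*"]))
_RES = f"(?:[{AA1}]|{AA3})"


def _aa1(token: str) -> str:
    return _AA3_TO_1.get(token, token)


_RE_NONSENSE = re.compile(rf"^p\.\(?({_RES})(\d+)(\*|Ter)\)?$")
_RE_FRAMESHIFT = re.compile(rf"^p\.\(?({_RES})(\d+)({_RES})?fs(\*|Ter)?\d*\)?$")
_RE_SUBST = re.compile(rf"^p\.\(?({_RES})(\d+)({_RES})\)?$")
_RE_INFRAME = re.compile(
    rf"^p\.\(?({_RES})(\d+)(?:_({_RES})(\d+))?(dup|del|ins[A-Za-z]*)\)?$"
)
_RE_SYN = re.compile(rf"^p\.\(?({_RES})(\d+)=\)?$")


def classify_consequence(hgvs_protein: str) -> str:
    """Classify an HGVS protein token into PTC / missense / inframe_indel / synonymous / other.

    Premature termination codons (PTC) cover nonsense (p.Q230*) and
    frameshift (p.E79Gfs*9) notations; in-frame duplications/deletions
    (p.G61_G62dup) are their own class. Unparseable tokens warn and fall
    into "other".
    """
    token = hgvs_protein.strip()
    if not token.startswith("p."):
        warnings.warn(f"not an HGVS protein token: {token!r}")
        return "other"
    if _RE_NONSENSE.match(token) or _RE_FRAMESHIFT.match(token):
        return "PTC"
    m = _RE_SYN.match(token)
    if m:
        return "synonymous"
    m = _RE_SUBST.match(token)
    if m:
        ref, alt = _aa1(m.group(1)), _aa1(m.group(3))
        if alt == "*":
            return "PTC"
        return "synonymous" if ref == alt else "missense"
    if _RE_INFRAME.match(token):
        return "inframe_indel"
    warnings.warn(f"unparseable HGVS protein token: {token!r}")
    return "other"


# ---------------------------------------------------------------------------
# Fisher allelic test


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    ci95: tuple[float, float]
    p_two_sided: float


def fisher_allelic(
    case_alt: int, case_total_alleles: int,
    control_alt: int, control_total_alleles: int,
) -> ContingencyResult:
    """Allelic Fisher exact test with OR and Woolf 95% CI.

    The two-sided p sums hypergeometric probabilities no larger than the
    observed table's (probability-mass method), computed in exact integer
    arithmetic. The odds ratio is the sample cross-product with a
    Haldane–Anscombe +0.5 on all cells when any cell is zero; the CI is the
    Woolf log-OR interval on the (possibly corrected) table.
    """
    a, c = case_alt, control_alt
    b = case_total_alleles - case_alt
    d = control_total_alleles - control_alt
    if min(a, b, c, d) < 0:
        raise ValidationError("alt counts must be within [0, total alleles]")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValidationError("empty table")
    # exact enumeration over the hypergeometric support with fixed margins
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    nums = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)}
    obs = nums[a]
    p = float(Fraction(sum(v for v in nums.values() if v <= obs), comb(n, c1)))

    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    or_ = (aa * dd) / (bb * cc)
    se = sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci = (exp(log(or_) - 1.96 * se), exp(log(or_) + 1.96 * se))
    return ContingencyResult(table=((a, b), (c, d)), odds_ratio=or_, ci95=ci,
                             p_two_sided=min(1.0, p))


# ---------------------------------------------------------------------------
# permutation burden (SKAT-O-style omnibus)


@dataclass(frozen=True)
class BurdenResult:
    statistic: float
    p_value: float
    rho_grid: tuple[float, ...]
    n_perm: int
    n_variants: int


def permutation_burden(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    weight_rule: str = "beta_1_25",
    n_perm: int = 2000,
    seed: int = 0,
    rho_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    maf_threshold: float = 0.01,
) -> BurdenResult:
    """Permutation omnibus rare-variant association test.

    For weighted per-variant score statistics s_j = w_j g_j^T (y - ybar), the
    statistic Q_rho = rho (sum s)^2 + (1-rho) sum s^2 interpolates between a
    burden test (rho=1) and a variance-component (SKAT-like) test (rho=0).
    Each Q_rho is standardized by its permutation moments and the omnibus
    statistic is the maximum over the rho grid; the p-value comes from
    phenotype-label permutation of the same maximum: (1 + #{perm >= obs}) /
    (n_perm + 1). Weights follow the Beta(MAF; 1, 25) convention.

    Variants with sample MAF >= ``maf_threshold`` are excluded (the test is
    defined for rare variation).
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if G.ndim != 2 or len(y) != G.shape[0]:
        raise ValidationError("genotypes must be n_samples x n_variants")
    if n_perm < 1000:
        raise ValidationError("n_perm must be >= 1000")
    if np.all(y == y[0]):
        raise ValidationError("constant phenotype")
    maf = G.mean(axis=0) / 2.0
    maf = np.minimum(maf, 1.0 - maf)
    keep = (maf < maf_threshold) & (maf > 0)
    if not keep.any():
        raise ValidationError("no polymorphic rare variants to test")
    G = G[:, keep]
    maf = maf[keep]
    if weight_rule == "beta_1_25":
        w = stats.beta.pdf(maf, 1, 25)
    elif weight_rule == "unweighted":
        w = np.ones_like(maf)
    else:
        raise ValidationError(f"unknown weight rule {weight_rule!r}")

    rng = np.random.default_rng(seed)
    u = y - y.mean()
    n = len(y)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    U = u[perm_idx].T  # n x n_perm permuted centred phenotypes
    S_obs = w * (G.T @ u)  # m
    S_perm = w[:, None] * (G.T @ U)  # m x n_perm

    rhos = np.asarray(rho_grid, dtype=float)
    q_obs = np.empty(len(rhos))
    q_perm = np.empty((len(rhos), n_perm))
    burden_obs, skat_obs = S_obs.sum() ** 2, (S_obs**2).sum()
    burden_perm = S_perm.sum(axis=0) ** 2
    skat_perm = (S_perm**2).sum(axis=0)
    for i, rho in enumerate(rhos):
        q_obs[i] = rho * burden_obs + (1 - rho) * skat_obs
        q_perm[i] = rho * burden_perm + (1 - rho) * skat_perm
    mu = q_perm.mean(axis=1, keepdims=True)
    sd = q_perm.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z_obs = float(((q_obs[:, None] - mu) / sd).max())
    z_perm = ((q_perm - mu) / sd).max(axis=0)
    # sparse genotypes make the statistic discrete: many permutations tie the
    # observed value exactly. Randomized tie-breaking gives the exact
    # (uniform) permutation p instead of a conservative one.
    tol = 1e-9 * max(1.0, abs(z_obs))
    n_greater = int(np.sum(z_perm > z_obs + tol))
    n_ties = int(np.sum(np.abs(z_perm - z_obs) <= tol))
    u_obs = rng.random()
    tie_wins = int(np.sum(rng.random(n_ties) >= u_obs)) if n_ties else 0
    p = (1.0 + n_greater + tie_wins) / (n_perm + 1.0)
    return BurdenResult(statistic=z_obs, p_value=float(p), rho_grid=tuple(rhos),
                        n_perm=n_perm, n_variants=G.shape[1])


# ---------------------------------------------------------------------------
# Mann-Whitney U


def mann_whitney_exact(
    group_a, group_b, exact_max: int = 10
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U; exact by full labeling enumeration when small.

    Exact enumeration over all C(n+m, n) group assignments runs when
    min(n, m) <= ``exact_max``; ties are handled with midranks (the
    enumeration is then permutation-exact). Larger samples use the
    tie-corrected normal approximation with continuity correction.
    Returns (U for group_a, p).
    """
    xs = np.asarray(group_a, dtype=float)
    ys = np.asarray(group_b, dtype=float)
    if len(xs) == 0 or len(ys) == 0:
        raise ValidationError("both groups must be non-empty")
    n, m = len(xs), len(ys)
    pool = np.concatenate([xs, ys])
    ranks = stats.rankdata(pool)
    u_a = float(ranks[:n].sum() - n * (n + 1) / 2)
    if min(n, m) <= exact_max:
        total = n + m
        centre = n * m / 2.0
        obs_dev = abs(u_a - centre)
        hits = 0
        count = 0
        rank_sum_offset = n * (n + 1) / 2
        for idx in combinations(range(total), n):
            u = ranks[list(idx)].sum() - rank_sum_offset
            count += 1
            if abs(u - centre) >= obs_dev - 1e-9:
                hits += 1
        return u_a, hits / count
    res = stats.mannwhitneyu(xs, ys, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return u_a, float(res.pvalue)


# ---------------------------------------------------------------------------
# chi-square familial-load test


def chi_square_test(table) -> tuple[float, float, int]:
    """Pearson chi-square on an RxC count table, no continuity correction.

    Returns (statistic, p, dof). Zero expected counts are an error — use
    the Fisher exact test for such sparse tables.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or (arr < 0).any():
        raise ValidationError("table must be a 2-D array of non-negative counts")
    expected = stats.contingency.expected_freq(arr)
    if (expected <= 0).any():
        raise ValidationError("zero expected count: use a Fisher exact test")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


# ---------------------------------------------------------------------------
# reference-gene normalization


def geometric_normalize(
    expression: pd.DataFrame, reference_genes: list[str]
) -> pd.DataFrame:
    """Normalize each sample (row) by the geometric mean of its reference genes.

    The multi-reference-gene geometric averaging convention used for qPCR
    normalization: every gene value in a sample is divided by that sample's
    geometric mean over ``reference_genes``. Scaling all of a sample's genes
    by a constant leaves the normalized values unchanged.
    """
    missing = [g for g in reference_genes if g not in expression.columns]
    if missing:
        raise ValidationError(f"reference genes absent: {missing}")
    if not reference_genes:
        raise ValidationError("reference_genes must be non-empty")
    ref = expression[reference_genes]
    if (ref <= 0).any().any():
        raise ValidationError("reference-gene expression must be positive")
    gm = np.exp(np.log(ref).mean(axis=1))
    return expression.div(gm, axis=0)
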