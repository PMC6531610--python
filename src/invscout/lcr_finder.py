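"""Inverted-repeat (IP-LCR) detection by seeded self-comparison.

A sequence is compared against its own reverse complement: shared k-mers
falling on a common anti-diagonal (position_a + partner_position constant)
betray an inverted repeat pair. Seeds are chained per anti-diagonal and
extended ungapped with +1/-2 scoring and x-drop termination — adequate for
the substitution-only repeat model, and fast enough for megabase-scale
self-comparison.

Inverted pairs that are long, nearly identical and separated by the right
distance are the substrate for non-allelic homologous recombination (NAHR),
the mechanism that mediates recurrent inversions; ``flag_nahr_susceptible``
applies those thresholds (identity > 98% by default).
"""
from __future__ import annotations

import numpy as np

from .model import Interval, RepeatHit, ValidationError

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def _encode(sequence: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValidationError("sequence contains characters outside ACGT")
    return codes.astype(np.int64)


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    n = len(codes)
    acc = np.zeros(n - k + 1, dtype=np.int64)
    for t in range(k):
        acc = acc * 4 + codes[t : n - k + 1 + t]
    return acc


def _rc_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    comp = 3 - codes
    n = len(codes)
    acc = np.zeros(n - k + 1, dtype=np.int64)
    for t in range(k):
        acc = acc * 4 + comp[k - 1 - t : n - t]
    return acc


def _seed_matches(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) with S[i:i+k] == revcomp(S[j:j+k]) and i + k <= j."""
    kv = _kmer_codes(codes, k)
    rckv = _rc_kmer_codes(codes, k)
    o1 = np.argsort(kv, kind="stable")
    o2 = np.argsort(rckv, kind="stable")
    s1, s2 = kv[o1], rckv[o2]
    common = np.intersect1d(s1, s2)
    l1 = np.searchsorted(s1, common, "left")
    r1 = np.searchsorted(s1, common, "right")
    l2 = np.searchsorted(s2, common, "left")
    r2 = np.searchsorted(s2, common, "right")
    ii, jj = [], []
    for t in range(len(common)):
        a = o1[l1[t] : r1[t]]
        b = o2[l2[t] : r2[t]]
        for i in a:
            for j in b:
                if i + k <= j:
                    ii.append(i)
                    jj.append(j)
    return np.asarray(ii, dtype=np.int64), np.asarray(jj, dtype=np.int64)


def _xdrop_end(match: np.ndarray, xdrop: float) -> int:
    """Index (exclusive) of the running-best score position under x-drop.

    ``match`` is a boolean array walked left→right from the extension origin.
    Returns how many positions to keep (0 if extension immediately drops).
    """
    if len(match) == 0:
        return 0
    step = np.where(match, 1.0, -2.0)
    score = np.cumsum(step)
    best = np.maximum.accumulate(score)
    dropped = best - score >= xdrop
    stop = int(np.argmax(dropped)) if dropped.any() else len(match)
    if stop == 0:
        return 0
    return int(np.argmax(score[:stop])) + 1


def find_inverted_repeats(
    sequence: str,
    k: int = 12,
    min_len_bp: int = 1000,
    min_identity_pct: float = 90.0,
    xdrop: float = 20.0,
    min_seeds: int = 3,
    max_chain_gap: int = 500,
) -> list[RepeatHit]:
    """Find inverted repeat pairs; each hit is reported once, interval_a leftmost."""
    if not 8 <= k <= 32:
        raise ValidationError("k must lie in [8, 32]")
    if min_len_bp < 100:
        raise ValidationError("min_len_bp must be >= 100")
    n = len(sequence)
    if n < max(min_len_bp, 2 * k):
        return []
    codes = _encode(sequence)
    comp = 3 - codes
    ii, jj = _seed_matches(codes, k)
    if len(ii) == 0:
        return []
    diag = ii + jj + k - 1  # anti-diagonal: p pairs with q = diag - p

    # group seeds into chains: nearby anti-diagonals (<= k apart), then runs
    # of seeds along the diagonal with bounded gaps
    order = np.lexsort((ii, diag))
    ii, diag = ii[order], diag[order]
    hits: list[RepeatHit] = []
    start = 0
    groups: list[tuple[np.ndarray, np.ndarray]] = []
    for t in range(1, len(diag) + 1):
        if t == len(diag) or diag[t] - diag[t - 1] > k:
            groups.append((ii[start:t], diag[start:t]))
            start = t
    for gi, gd in groups:
        o = np.argsort(gi, kind="stable")
        gi, gd = gi[o], gd[o]
        cstart = 0
        for t in range(1, len(gi) + 1):
            if t == len(gi) or gi[t] - gi[t - 1] > max_chain_gap:
                if t - cstart >= min_seeds:
                    hit = _extend_chain(
                        codes, comp, gi[cstart:t], gd[cstart:t], k, xdrop
                    )
                    if hit is not None:
                        hits.append(hit)
                cstart = t
    hits = [
        h for h in hits
        if h.aligned_len_bp >= min_len_bp and h.identity_pct >= min_identity_pct
        and h.interval_a.end <= h.interval_b.start
    ]
    return _dedupe(hits)


def _extend_chain(
    codes: np.ndarray,
    comp: np.ndarray,
    chain_i: np.ndarray,
    chain_d: np.ndarray,
    k: int,
    xdrop: float,
) -> RepeatHit | None:
    n = len(codes)
    d0 = int(np.median(chain_d))
    # valid copy_a positions p on this anti-diagonal: partner q = d0 - p
    p_lo_lim = max(0, d0 - (n - 1))
    p_hi_lim = (d0 - 1) // 2  # keep p strictly left of its partner
    if p_hi_lim < p_lo_lim:
        return None
    p = np.arange(p_lo_lim, p_hi_lim + 1)
    match = codes[p] == comp[d0 - p]

    core_lo = max(int(chain_i.min()), p_lo_lim) - p_lo_lim
    core_hi = min(int(chain_i.max()) + k - 1, p_hi_lim) - p_lo_lim
    keep_right = _xdrop_end(match[core_hi + 1 :], xdrop)
    keep_left = _xdrop_end(match[:core_lo][::-1], xdrop)
    lo = core_lo - keep_left
    hi = core_hi + keep_right
    span = match[lo : hi + 1]
    aligned_len = int(len(span))
    matches = int(span.sum())
    if aligned_len == 0:
        return None
    a_start = p_lo_lim + lo
    a_end = p_lo_lim + hi + 1
    b_start = d0 - (a_end - 1)
    b_end = d0 - a_start + 1
    if b_start < a_end:  # palindromic overlap near the centre: not a repeat pair
        return None
    return RepeatHit(
        interval_a=Interval(a_start, a_end),
        interval_b=Interval(b_start, b_end),
        identity_pct=100.0 * matches / aligned_len,
        aligned_len_bp=aligned_len,
        score=float(matches - 2 * (aligned_len - matches)),
    )


def _dedupe(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Collapse hits whose both intervals overlap; keep the best-scoring one."""
    hits = sorted(hits, key=lambda h: (-h.score, h.interval_a.start))
    kept: list[RepeatHit] = []
    for h in hits:
        if any(
            h.interval_a.overlaps(q.interval_a) and h.interval_b.overlaps(q.interval_b)
            for q in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.interval_a.start, h.interval_b.start))
    return kept


def flag_nahr_susceptible(
    hits: list[RepeatHit],
    min_len_bp: int = 1000,
    min_identity_pct: float = 98.0,
    min_sep_bp: int = 0,
    max_sep_bp: int = 10_000_000,
) -> list[RepeatHit]:
    """Subset of hits long/similar/spaced enough to mediate NAHR."""
    if min_sep_bp > max_sep_bp:
        raise ValidationError("min_sep_bp exceeds max_sep_bp")
    if min(min_len_bp, min_identity_pct) < 0:
        raise ValidationError("thresholds must be positive")
    return [
        h for h in hits
        if h.aligned_len_bp >= min_len_bp
        and h.identity_pct >= min_identity_pct
        and min_sep_bp <= h.separation_bp <= max_sep_bp
    ]
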