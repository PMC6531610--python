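"""Inversion calling from paired-end alignments.

An FR library maps mates on opposite strands at a characteristic distance.
An inversion flips the strand of any read falling inside it and mirrors its
position, so fragments straddling the proximal breakpoint become ++ pairs
(one mate just left of the proximal breakpoint, the other mirrored near the
distal one) and fragments straddling the distal breakpoint become -- pairs.
The caller calibrates the insert-size distribution robustly, classifies
pairs, clusters same-orientation discordant pairs by single linkage, and
emits a call when a ++ and a -- cluster localize compatible breakpoint
intervals.
"""
from __future__ import annotations

import numpy as np

from .model import (
    AlignedPair,
    DiscordantCluster,
    InsertSizeModel,
    Interval,
    InversionCall,
    ValidationError,
)

MAD_TO_SD = 1.4826  # consistency factor for a Normal distribution


def estimate_insert_model(
    pairs: list[AlignedPair], k_spread: float = 5.0
) -> InsertSizeModel:
    """Robust insert-size calibration from properly oriented (FR) pairs.

    Median and scaled MAD of |TLEN| over FR pairs only; the concordance
    window is median ± k_spread * spread.
    """
    tlens = np.array(
        [abs(p.template_len_bp) for p in pairs
         if p.strand1 != p.strand2 and not p.spanning_flag]
    )
    if len(tlens) < 100:
        raise ValidationError(
            f"insufficient FR pairs for calibration ({len(tlens)} < 100)"
        )
    med = float(np.median(tlens))
    spread = MAD_TO_SD * float(np.median(np.abs(tlens - med)))
    return InsertSizeModel(
        median_bp=med,
        spread_bp=spread,
        lower_bp=max(0.0, med - k_spread * spread),
        upper_bp=med + k_spread * spread,
    )


def classify_pair(pair: AlignedPair, model: InsertSizeModel) -> str:
    """One of concordant / discordant_distance / discordant_orientation / discordant_both."""
    bad_orient = pair.strand1 == pair.strand2
    bad_dist = not model.lower_bp <= abs(pair.template_len_bp) <= model.upper_bp
    if bad_orient and bad_dist:
        return "discordant_both"
    if bad_orient:
        return "discordant_orientation"
    if bad_dist:
        return "discordant_distance"
    return "concordant"


def _left_right(pair: AlignedPair) -> tuple[int, int]:
    """0-based starts of the leftmost and rightmost mates in reference space."""
    a, b = pair.pos1 - 1, pair.pos2 - 1
    return (a, b) if a <= b else (b, a)


def cluster_discordant(
    pairs: list[AlignedPair], max_gap_bp: float
) -> list[DiscordantCluster]:
    """Single-linkage clustering of orientation-discordant pairs.

    Clustering runs per orientation class (++ / --) on the leftmost mate
    coordinate; ``left_extent``/``right_extent`` span the leftmost and
    rightmost mate coordinates of the members.
    """
    if max_gap_bp <= 0:
        raise ValidationError("max_gap_bp must be positive")
    clusters: list[DiscordantCluster] = []
    for oc in ("++", "--"):
        members = sorted(
            (p for p in pairs if p.orientation_class == oc),
            key=lambda p: _left_right(p)[0],
        )
        run: list[AlignedPair] = []
        for p in members:
            if run and _left_right(p)[0] - _left_right(run[-1])[0] > max_gap_bp:
                clusters.append(_make_cluster(oc, run))
                run = []
            run.append(p)
        if run:
            clusters.append(_make_cluster(oc, run))
    return clusters


def _make_cluster(oc: str, members: list[AlignedPair]) -> DiscordantCluster:
    lefts = [_left_right(p)[0] for p in members]
    rights = [_left_right(p)[1] for p in members]
    rl = members[0].read_len_bp
    return DiscordantCluster(
        orientation_class=oc,
        members=list(members),
        left_extent=Interval(min(lefts), max(lefts) + rl),
        right_extent=Interval(min(rights), max(rights) + rl),
    )


def _proposals(
    cluster: DiscordantCluster, upper_bp: float, read_len: int
) -> tuple[Interval, Interval]:
    """Breakpoint localization intervals implied by one cluster.

    ++ pairs sit entirely left of each breakpoint (left mate left of the
    proximal, mirrored mate left of the distal), so the breakpoints lie
    within one insert size to the right of the maximal mate ends. -- pairs
    sit right of the breakpoints, bounding them from the other side. A pad
    of one read length absorbs the discreteness of fragment placement.
    """
    up = int(round(upper_bp))
    if cluster.orientation_class == "++":
        prox = Interval(max(0, cluster.left_extent.end - read_len),
                        cluster.left_extent.end + up)
        dist = Interval(max(0, cluster.right_extent.end - read_len),
                        cluster.right_extent.end + up)
    else:
        prox = Interval(max(0, cluster.left_extent.start - up),
                        cluster.left_extent.start + read_len)
        dist = Interval(max(0, cluster.right_extent.start - up),
                        cluster.right_extent.start + read_len)
    return prox, dist


def call_inversions(
    clusters: list[DiscordantCluster],
    model: InsertSizeModel,
    min_support: int = 3,
    chrom: str = "chrS",
) -> list[InversionCall]:
    """Pair ++ and -- clusters with compatible breakpoint proposals into calls.

    A matched ++/-- pair must propose intersecting proximal AND distal
    intervals; the call reports the intersections. An unmatched cluster with
    support >= 2 * min_support yields a one-sided call with its own (wider)
    proposals. Total support must reach ``min_support``.
    """
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    rl = clusters[0].members[0].read_len_bp if clusters else 0
    pp = [c for c in clusters if c.orientation_class == "++"]
    mm = [c for c in clusters if c.orientation_class == "--"]
    calls: list[InversionCall] = []
    used_pp: set[int] = set()
    used_mm: set[int] = set()
    for a_idx, a in enumerate(pp):
        pa, da = _proposals(a, model.upper_bp, rl)
        for b_idx, b in enumerate(mm):
            if b_idx in used_mm:
                continue
            pb, db = _proposals(b, model.upper_bp, rl)
            prox = pa.intersect(pb)
            dist = da.intersect(db)
            if prox is None or dist is None or prox.end > dist.start:
                continue
            if a.support + b.support < min_support:
                continue
            calls.append(
                InversionCall(
                    chrom=chrom, proximal=prox, distal=dist,
                    support_pp=a.support, support_mm=b.support,
                    evidence="short_read",
                )
            )
            used_pp.add(a_idx)
            used_mm.add(b_idx)
            break
    # one-sided fallback: a strong lone cluster still proposes an inversion
    for idx, c in enumerate(pp):
        if idx not in used_pp and c.support >= 2 * min_support:
            prox, dist = _proposals(c, model.upper_bp, rl)
            if prox.end <= dist.start:
                calls.append(
                    InversionCall(chrom=chrom, proximal=prox, distal=dist,
                                  support_pp=c.support, evidence="short_read",
                                  one_sided=True)
                )
    for idx, c in enumerate(mm):
        if idx not in used_mm and c.support >= 2 * min_support:
            prox, dist = _proposals(c, model.upper_bp, rl)
            if prox.end <= dist.start:
                calls.append(
                    InversionCall(chrom=chrom, proximal=prox, distal=dist,
                                  support_mm=c.support, evidence="short_read",
                                  one_sided=True)
                )
    calls.sort(key=lambda c: (c.proximal.start, c.distal.start))
    return calls


def call_from_pairs(
    pairs: list[AlignedPair],
    min_support: int = 3,
    k_spread: float = 5.0,
    min_mapq: int = 20,
    max_gap_bp: float | None = None,
    chrom: str | None = None,
) -> list[InversionCall]:
    """End-to-end short-read calling: calibrate, classify, cluster, call.

    Breakpoint-spanning clipped pairs and low-mapq pairs (ambiguity the
    repeat context causes in real data) are excluded before clustering.
    """
    model = estimate_insert_model(pairs, k_spread=k_spread)
    usable = [p for p in pairs if p.mapq >= min_mapq and not p.spanning_flag]
    discordant = [
        p for p in usable
        if classify_pair(p, model) in ("discordant_orientation", "discordant_both")
    ]
    gap = max_gap_bp if max_gap_bp is not None else max(model.upper_bp, 1.0)
    clusters = cluster_discordant(discordant, gap)
    clusters = [c for c in clusters if c.support >= 2]
    name = chrom or (pairs[0].chrom if pairs else "chrS")
    return call_inversions(clusters, model, min_support=min_support, chrom=name)
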