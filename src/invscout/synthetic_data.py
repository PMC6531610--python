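"""Synthetic genomes, alignments, pedigrees and cohorts with recorded ground truth.

Everything downstream of the simulators is tested against the ground truth
recorded here: planted inverted low-copy repeats (the NAHR substrate), a
paracentric inversion, analytically mapped paired-end and long-read
alignments, a three-generation autosomal-dominant family carrying a disease
haplotype, and rare-variant case/control cohorts under a logistic model.

Alignments are computed analytically from the inversion coordinates — no
base-level read simulation or aligner is involved. A read position in the
donor maps to the reference through a mirror reflection about each inversion
it falls in; reads that straddle a breakpoint are emitted clipped and
flagged as breakpoint-spanning.
"""
from __future__ import annotations

import zlib
from dataclasses import replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    AlignedPair,
    AlignmentSegment,
    InsertProfile,
    Interval,
    InversionEvent,
    LCRPair,
    LongReadAlignment,
    PedigreeSample,
    SyntheticGenome,
    ValidationError,
    VariantRecord,
    revcomp,
)

BASES = np.array(["A", "C", "G", "T"])


def derive_seed(master_seed: int, tag: str) -> int:
    """Stable per-stage seed derived from a master seed and a stage label."""
    return int(
        np.random.SeedSequence([int(master_seed), zlib.crc32(tag.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


# ---------------------------------------------------------------------------
# genome construction


def generate_genome(
    length_bp: int, gc_fraction: float = 0.5, seed: int = 0, name: str = "chrS"
) -> SyntheticGenome:
    """Generate an i.i.d. random genome with the requested GC content."""
    if length_bp < 1000:
        raise ValidationError("length_bp must be >= 1000")
    if not 0 < gc_fraction < 1:
        raise ValidationError("gc_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    seq = "".join(rng.choice(BASES, size=length_bp, p=[at, gc, gc, at]))
    return SyntheticGenome(name=name, sequence=seq, seed=seed)


def _mutate_substitutions(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    """Substitute exactly n_mut distinct positions with a different base."""
    if n_mut == 0:
        return seq
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(3)]
    return "".join(arr)


def plant_inverted_lcr(
    genome: SyntheticGenome,
    copy_len_bp: int,
    separation_bp: int,
    identity_pct: float = 98.0,
    anchor_bp: int = 0,
    seed: int = 0,
) -> SyntheticGenome:
    """Plant an inverted paralogous repeat pair (copy_b = mutated revcomp of copy_a).

    The per-base substitution rate applied to copy_b is (100 - identity_pct)%,
    as an exact count, so the planted Hamming identity matches ``identity_pct``
    up to rounding.
    """
    end = anchor_bp + 2 * copy_len_bp + separation_bp
    if anchor_bp < 0 or end > len(genome):
        raise ValidationError("LCR pair does not fit in the genome")
    if not 0 <= identity_pct <= 100:
        raise ValidationError("identity_pct outside [0, 100]")
    rng = np.random.default_rng(seed)
    a = Interval(anchor_bp, anchor_bp + copy_len_bp)
    b = Interval(a.end + separation_bp, a.end + separation_bp + copy_len_bp)
    copy_a = genome.sequence[a.start : a.end]
    n_mut = int(round((100.0 - identity_pct) / 100.0 * copy_len_bp))
    copy_b = _mutate_substitutions(revcomp(copy_a), n_mut, rng)
    seq = genome.sequence[: b.start] + copy_b + genome.sequence[b.end :]
    pair = LCRPair(
        copy_a=a,
        copy_b=b,
        orientation="inverted",
        identity_pct=100.0 - 100.0 * n_mut / copy_len_bp,
        separation_bp=separation_bp,
    )
    return SyntheticGenome(
        name=genome.name,
        sequence=seq,
        lcr_pairs=genome.lcr_pairs + [pair],
        inversions=list(genome.inversions),
        seed=genome.seed,
    )


def apply_inversion(
    genome: SyntheticGenome, start: int, end: int, mechanism: str = "arbitrary"
) -> SyntheticGenome:
    """Reverse-complement the segment [start, end) and record the event."""
    if not 0 <= start < end <= len(genome):
        raise ValidationError("inversion bounds outside genome")
    seq = (
        genome.sequence[:start]
        + revcomp(genome.sequence[start:end])
        + genome.sequence[end:]
    )
    ev = InversionEvent(start=start, end=end, mechanism=mechanism)
    return SyntheticGenome(
        name=genome.name,
        sequence=seq,
        lcr_pairs=list(genome.lcr_pairs),
        inversions=genome.inversions + [ev],
        seed=genome.seed,
    )


def nahr_inversion_bounds(pair: LCRPair, rng: np.random.Generator) -> tuple[int, int]:
    """Draw NAHR-style breakpoints: one inside each LCR copy."""
    start = int(rng.integers(pair.copy_a.start + 1, pair.copy_a.end))
    end = int(rng.integers(pair.copy_b.start + 1, pair.copy_b.end))
    return start, end


# ---------------------------------------------------------------------------
# coordinate reflection


def map_donor_point(pos: int, inversions: Sequence[InversionEvent]) -> tuple[int, bool]:
    """Map a donor coordinate to reference space.

    Returns (reference position, flipped). Inversions must be non-overlapping;
    the mirror p -> start + end - 1 - p applies inside each event. The map is
    an involution, so it also sends reference coordinates back to the donor.
    """
    flipped = False
    for ev in inversions:
        if ev.start <= pos < ev.end:
            pos = ev.start + ev.end - 1 - pos
            flipped = not flipped
    return pos, flipped


def map_donor_interval(
    start: int, end: int, inversions: Sequence[InversionEvent]
) -> Optional[tuple[int, int, bool]]:
    """Map a donor interval wholly inside or outside every inversion.

    Returns (ref_start, ref_end, flipped) or None when the interval straddles
    a breakpoint (the caller must split it first).
    """
    flipped = False
    for ev in inversions:
        inside_start = ev.start <= start < ev.end
        inside_last = ev.start <= end - 1 < ev.end
        if inside_start != inside_last:
            return None
        if inside_start:
            start, end = ev.start + ev.end - end, ev.start + ev.end - start
            flipped = not flipped
    return start, end, flipped


def _split_at_breakpoints(
    start: int, end: int, inversions: Sequence[InversionEvent]
) -> list[tuple[int, int]]:
    """Split a donor interval at every inversion boundary inside it."""
    cuts = {start, end}
    for ev in inversions:
        for b in (ev.start, ev.end):
            if start < b < end:
                cuts.add(b)
    edges = sorted(cuts)
    return list(zip(edges[:-1], edges[1:]))


# ---------------------------------------------------------------------------
# paired-end simulation


def simulate_paired_end_alignments(
    reference: SyntheticGenome,
    donor: SyntheticGenome,
    coverage_x: float,
    profile: InsertProfile = InsertProfile(),
    seed: int = 0,
) -> list[AlignedPair]:
    """Simulate an FR paired-end library from the donor, mapped analytically.

    Fragment starts are uniform over the donor; insert sizes are
    Normal(mean_bp, sd_bp). Reads wholly inside an inverted segment are
    mirrored (position reflected, strand flipped); reads overlapping a
    breakpoint are emitted clipped, positioned on their longest mapped
    piece and flagged ``spanning``.
    """
    if len(reference) != len(donor):
        raise ValidationError("reference/donor length mismatch")
    if coverage_x <= 0:
        raise ValidationError("coverage must be positive")
    L = len(donor)
    rl = profile.read_len_bp
    rng = np.random.default_rng(seed)
    n_pairs = int(round(coverage_x * L / (2 * rl)))
    isize = np.clip(
        np.rint(rng.normal(profile.mean_bp, profile.sd_bp, size=n_pairs)).astype(int),
        2 * rl,
        L,
    )
    frag_start = rng.integers(0, L - isize + 1)
    inversions = donor.inversions

    pairs: list[AlignedPair] = []
    for i in range(n_pairs):
        f, ins = int(frag_start[i]), int(isize[i])
        # read 1 is the forward (left) end of the fragment, read 2 the reverse end
        r1 = _map_read(f, f + rl, "+", inversions)
        r2 = _map_read(f + ins - rl, f + ins, "-", inversions)
        pos1, strand1, span1 = r1
        pos2, strand2, span2 = r2
        left = min(pos1, pos2)
        right = max(pos1 + rl, pos2 + rl)
        tlen = (right - left) if pos1 <= pos2 else -(right - left)
        pairs.append(
            AlignedPair(
                pair_id=f"sim{i:07d}",
                chrom=reference.name,
                pos1=pos1 + 1,
                strand1=strand1,
                pos2=pos2 + 1,
                strand2=strand2,
                read_len_bp=rl,
                template_len_bp=tlen,
                mapq=60,
                spanning_flag=span1 or span2,
            )
        )
    return pairs


def _map_read(
    start: int, end: int, donor_strand: str, inversions: Sequence[InversionEvent]
) -> tuple[int, str, bool]:
    """Reference-space (0-based pos, strand, spanning) for one donor read."""
    mapped = map_donor_interval(start, end, inversions)
    if mapped is not None:
        ref_s, _ref_e, flipped = mapped
        strand = _flip(donor_strand) if flipped else donor_strand
        return ref_s, strand, False
    # breakpoint-spanning: anchor on the longest clean piece, flag it
    pieces = _split_at_breakpoints(start, end, inversions)
    best = max(pieces, key=lambda p: p[1] - p[0])
    ref_s, _ref_e, flipped = map_donor_interval(best[0], best[1], inversions)
    strand = _flip(donor_strand) if flipped else donor_strand
    return ref_s, strand, True


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


# ---------------------------------------------------------------------------
# long-read simulation


def simulate_long_read_alignments(
    reference: SyntheticGenome,
    donor: SyntheticGenome,
    n_reads: int,
    length_law: tuple = ("constant", 20000),
    seed: int = 0,
) -> list[LongReadAlignment]:
    """Simulate segmented long-read alignments.

    A read spanning k inversion breakpoints yields k+1 segments with
    alternating strands; reference intervals come from the same mirror
    reflection as the paired-end simulator. ``length_law`` is either
    ("constant", L) or ("lognormal", mu, sigma) on the natural-log scale.
    """
    if len(reference) != len(donor):
        raise ValidationError("reference/donor length mismatch")
    if n_reads <= 0:
        raise ValidationError("n_reads must be positive")
    L = len(donor)
    rng = np.random.default_rng(seed)
    if length_law[0] == "constant":
        lengths = np.full(n_reads, int(length_law[1]))
    elif length_law[0] == "lognormal":
        lengths = np.rint(rng.lognormal(length_law[1], length_law[2], n_reads)).astype(int)
    else:
        raise ValidationError(f"unknown length law {length_law[0]!r}")
    lengths = np.clip(lengths, 500, L)
    starts = rng.integers(0, L - lengths + 1)

    reads: list[LongReadAlignment] = []
    for i in range(n_reads):
        a, b = int(starts[i]), int(starts[i] + lengths[i])
        segments = []
        for s, e in _split_at_breakpoints(a, b, donor.inversions):
            ref_s, ref_e, flipped = map_donor_interval(s, e, donor.inversions)
            segments.append(
                AlignmentSegment(
                    read_start=s - a,
                    read_end=e - a,
                    ref_start=ref_s,
                    ref_end=ref_e,
                    strand="-" if flipped else "+",
                )
            )
        reads.append(
            LongReadAlignment(
                read_id=f"lr{i:06d}", chrom=reference.name, segments=segments,
                read_len_bp=b - a,
            )
        )
    return reads


def long_read_count_for_coverage(
    genome_bp: int, coverage_x: float, read_len_bp: int
) -> int:
    """Number of reads of a given length to reach a target mean coverage."""
    return max(1, int(round(coverage_x * genome_bp / read_len_bp)))


# ---------------------------------------------------------------------------
# pedigree & family variants


def default_pedigree() -> list[PedigreeSample]:
    """Three-generation autosomal-dominant family template.

    Shape mirrors a dominant dementia family with four sequenced affected
    members in three generation-III sibships; the founders of generation I
    are not genotyped (deceased).
    """
    P = PedigreeSample
    ped = [
        P("I-1", generation=1, affection="affected", carries_disease_haplotype=True,
          genotyped=False),
        P("I-2", generation=1, affection="unaffected", genotyped=False),
    ]
    # generation II: three affected carrier sibs + one unaffected sib, with spouses
    for idx, (sib, carrier) in enumerate(
        [("II-1", True), ("II-3", True), ("II-5", True), ("II-7", False)], start=1
    ):
        ped.append(
            P(sib, father="I-1", mother="I-2", generation=2,
              affection="affected" if carrier else "unaffected",
              carries_disease_haplotype=carrier)
        )
    for spouse in ("II-2", "II-4", "II-6"):
        ped.append(P(spouse, generation=2, affection="unaffected"))
    # generation III: three sibships, four affected carriers sequenced downstream
    trios = [
        ("II-1", "II-2", [("III-1", True), ("III-2", False)]),
        ("II-3", "II-4", [("III-3", True), ("III-4", True), ("III-5", False)]),
        ("II-5", "II-6", [("III-6", True), ("III-7", False)]),
    ]
    for father, mother, kids in trios:
        for kid, carrier in kids:
            ped.append(
                P(kid, father=father, mother=mother, generation=3,
                  affection="affected" if carrier else "unaffected",
                  carries_disease_haplotype=carrier)
            )
    return ped


SEQUENCED_AFFECTEDS = ["III-1", "III-3", "III-4", "III-6"]


def validate_pedigree(pedigree: Sequence[PedigreeSample]) -> None:
    ids = {p.sample_id for p in pedigree}
    by_id = {p.sample_id: p for p in pedigree}
    if not pedigree:
        raise ValidationError("empty pedigree")
    if not any(p.carries_disease_haplotype and p.father is None and p.mother is None
               for p in pedigree):
        raise ValidationError("no founder carries the disease haplotype")
    for p in pedigree:
        if p.father in ids and p.mother in ids and p.carries_disease_haplotype:
            if not (by_id[p.father].carries_disease_haplotype
                    or by_id[p.mother].carries_disease_haplotype):
                raise ValidationError(
                    f"{p.sample_id} carries the haplotype but neither parent does"
                )


def simulate_family_variants(
    pedigree: Sequence[PedigreeSample],
    locus: Interval,
    n_linked_unique: int = 4,
    n_linked_shared_polymorphic: int = 34,
    n_offlocus: int = 100,
    panel_maf_law: tuple = ("log_uniform", 1e-4, 9e-3),
    seed: int = 0,
    n_linked_noncosegregating: int = 41,
    n_control_samples: int = 50,
    chrom: str = "chrS",
    chrom_len: Optional[int] = None,
    panel_name: str = "panel",
) -> tuple[list[VariantRecord], dict[str, str]]:
    """Simulate a multi-sample family + control variant table with truth labels.

    Variant classes:

    * ``linked_unique`` — ride the disease haplotype, absent from panels and
      from every genotyped control.
    * ``linked_shared`` — ride the haplotype but are polymorphic (panel
      MAF < 1%, present in at least one genotyped control).
    * ``linked_noncoseg`` — in-locus, heterozygous in the sequenced affecteds
      but also carried by a genotyped married-in founder, so they fail
      co-segregation in the wider family.
    * ``offlocus`` — gene-dropped through the pedigree independently of
      affection, outside the locus.
    """
    validate_pedigree(pedigree)
    if min(n_linked_unique, n_linked_shared_polymorphic, n_offlocus,
           n_linked_noncosegregating) < 0:
        raise ValidationError("variant class counts must be non-negative")
    rng = np.random.default_rng(seed)
    by_id = {p.sample_id: p for p in pedigree}
    fam_ids = [p.sample_id for p in pedigree]
    ctrl_ids = [f"CTRL{i:03d}" for i in range(1, n_control_samples + 1)]
    if chrom_len is None:
        chrom_len = locus.end + max(1_000_000, len(locus))

    n_linked = n_linked_unique + n_linked_shared_polymorphic + n_linked_noncosegregating
    linked_pos = np.sort(rng.choice(np.arange(locus.start, locus.end),
                                    size=n_linked, replace=False))
    off_space = np.concatenate(
        [np.arange(0, locus.start), np.arange(locus.end, chrom_len)]
    )
    off_pos = np.sort(rng.choice(off_space, size=n_offlocus, replace=False))

    # married-in genotyped founders, usable as Mendelian-safe segregation violators
    founders_in = [
        p.sample_id for p in pedigree
        if p.father is None and p.mother is None and p.genotyped
        and not p.carries_disease_haplotype
    ]
    if n_linked_noncosegregating > 0 and not founders_in:
        raise ValidationError(
            "pedigree lacks a genotyped non-carrier founder for non-cosegregating "
            "variants"
        )

    def draw_maf() -> float:
        law = panel_maf_law
        if law[0] == "log_uniform":
            return float(10 ** rng.uniform(np.log10(law[1]), np.log10(law[2])))
        if law[0] == "fixed":
            return float(law[1])
        raise ValidationError(f"unknown MAF law {law[0]!r}")

    def haplotype_genotypes() -> dict[str, str]:
        gts = {}
        for p in pedigree:
            if not p.genotyped:
                gts[p.sample_id] = "./."
            else:
                gts[p.sample_id] = "0/1" if p.carries_disease_haplotype else "0/0"
        return gts

    def gene_drop(maf: float) -> dict[str, str]:
        """Mendelian gene-dropping of a bi-allelic autosomal variant."""
        alleles: dict[str, tuple[int, int]] = {}

        def resolve(pid: str) -> tuple[int, int]:
            if pid in alleles:
                return alleles[pid]
            p = by_id[pid]
            if p.father in by_id and p.mother in by_id:
                fa, mo = resolve(p.father), resolve(p.mother)
                al = (fa[rng.integers(2)], mo[rng.integers(2)])
            else:
                al = tuple(rng.binomial(1, maf, size=2))
            alleles[pid] = al
            return al

        gts = {}
        for p in pedigree:
            a, b = resolve(p.sample_id)
            if not p.genotyped:
                gts[p.sample_id] = "./."
            else:
                gts[p.sample_id] = ("0/0", "0/1", "1/1")[a + b]
        return gts

    def control_genotypes(maf: float, force_one_carrier: bool) -> dict[str, str]:
        gts = {}
        counts = rng.binomial(2, maf, size=len(ctrl_ids))
        if force_one_carrier and counts.sum() == 0:
            counts[rng.integers(len(ctrl_ids))] = 1
        for cid, c in zip(ctrl_ids, counts):
            gts[cid] = ("0/0", "0/1", "1/1")[c]
        return gts

    records: list[VariantRecord] = []
    truth: dict[str, str] = {}
    classes = (
        ["linked_unique"] * n_linked_unique
        + ["linked_shared"] * n_linked_shared_polymorphic
        + ["linked_noncoseg"] * n_linked_noncosegregating
    )
    rng.shuffle(classes)
    ref_alt = [("A", "G"), ("C", "T"), ("G", "T"), ("T", "C")]
    for pos, cls in zip(linked_pos, classes):
        vid = f"var_{chrom}_{int(pos) + 1}"
        ref, alt = ref_alt[rng.integers(len(ref_alt))]
        gts = haplotype_genotypes()
        if cls == "linked_unique":
            maf = 0.0
            gts.update({c: "0/0" for c in ctrl_ids})
        elif cls == "linked_shared":
            maf = draw_maf()
            gts.update(control_genotypes(maf, force_one_carrier=True))
        else:  # linked_noncoseg: an extra carrier among married-in founders
            maf = draw_maf()
            gts[founders_in[rng.integers(len(founders_in))]] = "0/1"
            gts.update(control_genotypes(maf, force_one_carrier=False))
        records.append(
            VariantRecord(
                chrom=chrom, pos=int(pos) + 1, ref_allele=ref, alt_allele=alt,
                var_id=vid, quality=100.0, panel_freqs={panel_name: maf},
                genotypes=gts,
            )
        )
        truth[vid] = cls
    for pos in off_pos:
        vid = f"var_{chrom}_{int(pos) + 1}"
        ref, alt = ref_alt[rng.integers(len(ref_alt))]
        maf = draw_maf()
        gts = gene_drop(maf)
        gts.update(control_genotypes(maf, force_one_carrier=False))
        records.append(
            VariantRecord(
                chrom=chrom, pos=int(pos) + 1, ref_allele=ref, alt_allele=alt,
                var_id=vid, quality=100.0, panel_freqs={panel_name: maf},
                genotypes=gts,
            )
        )
        truth[vid] = "offlocus"
    records.sort(key=lambda r: r.pos)
    return records, truth


# ---------------------------------------------------------------------------
# case/control burden cohort


def simulate_case_control_genotypes(
    n_cases: int,
    n_controls: int,
    region_bp: int = 3545,
    causal_pct: float = 40.0,
    protective_pct: float = 10.0,
    max_or: float = 5.0,
    maf_law: tuple = ("log_uniform", 1e-4, 9e-3),
    seed: int = 0,
    n_variants: Optional[int] = None,
    baseline_prevalence: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate rare-variant genotypes and a logistic case/control phenotype.

    Defaults follow the power-simulation scenario used for the target gene:
    a 3545 bp region, 40% causal and 10% protective variants, maximal odds
    ratio 5. Per-variant log odds ratios scale with \\|log10 MAF\\| so the
    rarest effect variant attains ``max_or``. Cases and controls are filled
    by rejection sampling from the population model, which preserves the
    per-variant odds ratios under case-control ascertainment.

    Returns (genotype matrix n x m with values 0/1/2, phenotype 0/1 vector,
    info dict with keys maf/role/beta/pos).
    """
    if causal_pct < 0 or protective_pct < 0 or causal_pct + protective_pct > 100:
        raise ValidationError("causal_pct + protective_pct must be <= 100")
    if max_or <= 1:
        raise ValidationError("max_or must exceed 1")
    if n_cases <= 0 or n_controls <= 0:
        raise ValidationError("cohort sizes must be positive")
    rng = np.random.default_rng(seed)
    m = n_variants if n_variants is not None else max(1, region_bp // 100)
    if maf_law[0] == "log_uniform":
        mafs = 10 ** rng.uniform(np.log10(maf_law[1]), np.log10(maf_law[2]), size=m)
    elif maf_law[0] == "fixed":
        mafs = np.full(m, float(maf_law[1]))
    else:
        raise ValidationError(f"unknown MAF law {maf_law[0]!r}")
    pos = np.sort(rng.choice(region_bp, size=min(m, region_bp), replace=False))
    if len(pos) < m:  # more variants than distinct positions: recycle
        pos = np.sort(rng.integers(0, region_bp, size=m))

    roles = np.array(["neutral"] * m, dtype=object)
    n_causal = int(round(m * causal_pct / 100.0))
    n_prot = int(round(m * protective_pct / 100.0))
    effect_idx = rng.choice(m, size=n_causal + n_prot, replace=False)
    roles[effect_idx[:n_causal]] = "causal"
    roles[effect_idx[n_causal:]] = "protective"

    beta = np.zeros(m)
    if len(effect_idx) > 0:
        scale = np.abs(np.log10(mafs))
        ref = scale[effect_idx].max()
        beta[effect_idx] = np.log(max_or) * scale[effect_idx] / ref
        beta[effect_idx[n_causal:]] *= -1.0
    b0 = np.log(baseline_prevalence / (1 - baseline_prevalence))

    G_cases, G_ctrls = [], []
    need_ca, need_co = n_cases, n_controls
    max_batches = 1000
    batch = max(2048, 4 * (n_cases + n_controls))
    for _ in range(max_batches):
        if need_ca <= 0 and need_co <= 0:
            break
        G = rng.binomial(2, mafs, size=(batch, m)).astype(np.int8)
        eta = b0 + G @ beta
        y = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        if need_ca > 0:
            take = G[y][:need_ca]
            G_cases.append(take)
            need_ca -= len(take)
        if need_co > 0:
            take = G[~y][:need_co]
            G_ctrls.append(take)
            need_co -= len(take)
    if need_ca > 0 or need_co > 0:
        raise ValidationError("failed to fill case/control quotas; raise prevalence")
    genotypes = np.vstack(G_cases + G_ctrls)
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    info = {"maf": mafs, "role": roles, "beta": beta, "pos": pos}
    return genotypes, phenotype, info
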