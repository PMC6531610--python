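"""Domain types shared across the inversion-discovery pipeline.

Coordinates are 0-based half-open everywhere in memory; SAM/VCF export
converts to 1-based. Strands are "+" / "-".
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValidationError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def intersect(self, other: "Interval") -> Optional["Interval"]:
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return Interval(lo, hi) if lo < hi else None


@dataclass(frozen=True)
class LCRPair:
    """A pair of low-copy-repeat copies on one chromosome.

    ``copy_a`` lies strictly left of ``copy_b``; ``orientation`` is
    "inverted" when copy_b is the (mutated) reverse complement of copy_a —
    the NAHR-prone configuration.
    """

    copy_a: Interval
    copy_b: Interval
    orientation: str  # {"inverted", "direct"}
    identity_pct: float
    separation_bp: int

    def __post_init__(self) -> None:
        if self.copy_a.end > self.copy_b.start:
            raise ValidationError("copy_a must precede copy_b without overlap")
        if self.separation_bp != self.copy_b.start - self.copy_a.end:
            raise ValidationError("separation_bp inconsistent with intervals")
        if not 0 <= self.identity_pct <= 100:
            raise ValidationError("identity_pct outside [0, 100]")


@dataclass(frozen=True)
class InversionEvent:
    """A planted paracentric inversion: segment [start, end) reverse-complemented."""

    start: int
    end: int
    mechanism: str = "arbitrary"  # {"nahr", "arbitrary"}

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError("inversion requires 0 <= start < end")


@dataclass
class SyntheticGenome:
    """A simulated reference (or donor) chromosome with recorded ground truth."""

    name: str
    sequence: str
    lcr_pairs: list[LCRPair] = field(default_factory=list)
    inversions: list[InversionEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError("empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class InsertProfile:
    """Paired-end library model: FR ("innie") orientation, Normal insert sizes."""

    mean_bp: float = 350.0
    sd_bp: float = 35.0
    read_len_bp: int = 100
    orientation: str = "FR"
    per_base_error: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_bp < 2 * self.read_len_bp:
            raise ValidationError("insert mean must cover two reads")
        if self.sd_bp < 0:
            raise ValidationError("negative insert sd")
        if not 0 <= self.per_base_error < 0.1:
            raise ValidationError("per_base_error outside [0, 0.1)")
        if self.orientation != "FR":
            raise ValidationError("only FR libraries are modelled")


@dataclass
class AlignedPair:
    """One paired-end alignment in reference space.

    ``pos1``/``pos2`` are 1-based leftmost mapped positions of the two mates;
    ``template_len_bp`` is the signed outer span (positive for the leftmost
    mate, SAM TLEN convention). ``spanning_flag`` marks pairs with a read
    clipped at an inversion breakpoint.
    """

    pair_id: str
    chrom: str
    pos1: int
    strand1: str
    pos2: int
    strand2: str
    read_len_bp: int
    template_len_bp: int
    mapq: int = 60
    spanning_flag: bool = False

    def __post_init__(self) -> None:
        if self.pos1 < 1 or self.pos2 < 1:
            raise ValidationError("SAM positions are 1-based")
        if not 0 <= self.mapq <= 60:
            raise ValidationError("mapq outside [0, 60]")
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValidationError("strand must be '+' or '-'")

    @property
    def orientation_class(self) -> str:
        """"FR"-style label of the strand combination, e.g. "+-", "++"."""
        return self.strand1 + self.strand2


@dataclass(frozen=True)
class AlignmentSegment:
    """One aligned block of a (possibly split) long read."""

    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.read_end <= self.read_start or self.ref_end <= self.ref_start:
            raise ValidationError("degenerate alignment segment")


@dataclass
class LongReadAlignment:
    """A long read as an ordered list of reference-space segments."""

    read_id: str
    chrom: str
    segments: list[AlignmentSegment]
    read_len_bp: int

    def __post_init__(self) -> None:
        prev_end = 0
        for seg in self.segments:
            if seg.read_start < prev_end:
                raise ValidationError("read intervals overlap or are unordered")
            prev_end = seg.read_end


@dataclass
class VariantRecord:
    """One bi-allelic variant with per-sample genotypes and panel frequencies."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    var_id: str = "."
    quality: float = 100.0
    panel_freqs: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, str] = field(default_factory=dict)  # {"0/0","0/1","1/1","./."}
    annotations: dict[str, str] = field(default_factory=dict)

    def genotype(self, sample: str) -> str:
        return self.genotypes.get(sample, "./.")

    def is_carrier(self, sample: str) -> bool:
        """True only for an observed non-reference genotype (./., 0/0 -> False)."""
        return self.genotype(sample) in ("0/1", "1/1")


@dataclass(frozen=True)
class PedigreeSample:
    """One pedigree member with disease-haplotype ground truth."""

    sample_id: str
    father: Optional[str] = None
    mother: Optional[str] = None
    generation: int = 1
    affection: str = "unknown"  # {"affected", "unaffected", "unknown"}
    carries_disease_haplotype: bool = False
    genotyped: bool = True
    aao_years: Optional[float] = None
    aai_years: Optional[float] = None


@dataclass
class InsertSizeModel:
    """Robust insert-size calibration for an FR library."""

    median_bp: float
    spread_bp: float  # 1.4826 * MAD
    lower_bp: float
    upper_bp: float
    proper_orientation: str = "FR"


@dataclass
class DiscordantCluster:
    """Single-linkage cluster of same-orientation discordant pairs."""

    orientation_class: str  # {"++", "--"}
    members: list[AlignedPair]
    left_extent: Interval
    right_extent: Interval

    @property
    def support(self) -> int:
        return len(self.members)


@dataclass
class InversionCall:
    """A called inversion with breakpoint localization intervals."""

    chrom: str
    proximal: Interval
    distal: Interval
    support_pp: int = 0
    support_mm: int = 0
    evidence: str = "short_read"  # {"short_read", "long_read", "both"}
    one_sided: bool = False

    def __post_init__(self) -> None:
        if self.proximal.end > self.distal.start:
            raise ValidationError("proximal interval must lie left of distal")

    @property
    def support(self) -> int:
        return self.support_pp + self.support_mm

    def contains_truth(self, prox_bp: int, dist_bp: int) -> bool:
        """Do the reported intervals localize the true breakpoints?"""
        return self.proximal.contains(prox_bp) and self.distal.contains(dist_bp)


@dataclass(frozen=True)
class RepeatHit:
    """An inverted-repeat pair found by self-comparison."""

    interval_a: Interval
    interval_b: Interval
    identity_pct: float
    aligned_len_bp: int
    score: float

    @property
    def separation_bp(self) -> int:
        return self.interval_b.start - self.interval_a.end


__all__ = [
    "AlignedPair",
    "AlignmentSegment",
    "DiscordantCluster",
    "InsertProfile",
    "InsertSizeModel",
    "Interval",
    "InversionCall",
    "InversionEvent",
    "LCRPair",
    "LongReadAlignment",
    "PedigreeSample",
    "RepeatHit",
    "SyntheticGenome",
    "ValidationError",
    "VariantRecord",
    "revcomp",
]
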