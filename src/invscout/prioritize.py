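"""Family-based rare-variant prioritization cascade.

The cascade reproduces the discovery logic of a dominant-family WGS study:
keep good-quality variants, rare (MAF < 1%) in every reference panel or
absent from all of them, heterozygous in and shared by all sequenced
affected relatives, inside the linkage locus, co-segregating with the
disease haplotype in the wider genotyped family, and finally absent from
genotyped control individuals. Per-stage survivor counts are recorded so
the funnel (e.g. 79 in-locus shared variants → 38 co-segregating → 4
family-unique) is auditable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import Interval, PedigreeSample, ValidationError, VariantRecord

STAGE_ORDER = [
    "quality",
    "rarity",
    "zygosity",
    "sharing",
    "locus",
    "segregation",
    "control_absence",
]


@dataclass
class FilterConfig:
    """Configuration of the prioritization cascade."""

    sequenced_affecteds: list[str]
    min_quality: float = 30.0
    maf_threshold: float = 0.01  # strict "<"
    required_zygosity: str = "heterozygous"
    locus: Optional[Interval] = None
    control_samples: list[str] = field(default_factory=list)
    panels: Optional[list[str]] = None  # None: every panel present on a variant
    missing_fails_sharing: bool = True
    missing_passes_control: bool = True

    def __post_init__(self) -> None:
        if not self.sequenced_affecteds:
            raise ValidationError("sequenced_affecteds must be non-empty")
        if not 0 < self.maf_threshold <= 0.5:
            raise ValidationError("maf_threshold outside (0, 0.5]")


@dataclass
class FilterReport:
    """Ordered per-stage accounting of the cascade."""

    stages: list[str] = field(default_factory=list)
    n_in: dict[str, int] = field(default_factory=dict)
    n_out: dict[str, int] = field(default_factory=dict)
    survivors: dict[str, list[str]] = field(default_factory=dict)

    def record(self, stage: str, before: Sequence[VariantRecord],
               after: Sequence[VariantRecord]) -> None:
        self.stages.append(stage)
        self.n_in[stage] = len(before)
        self.n_out[stage] = len(after)
        self.survivors[stage] = [v.var_id for v in after]

    @property
    def final_survivors(self) -> list[str]:
        return self.survivors[self.stages[-1]] if self.stages else []

    def as_rows(self) -> list[tuple[str, int, int]]:
        return [(s, self.n_in[s], self.n_out[s]) for s in self.stages]


def check_segregation(
    variant: VariantRecord, pedigree: Sequence[PedigreeSample]
) -> str:
    """Classify a variant against the disease haplotype: segregates / violates / uninformative.

    Segregation requires every genotyped haplotype carrier to carry the
    variant and every genotyped non-carrier to be homozygous reference;
    any contradiction is a violation. Fewer than two informative genotyped
    samples leave the variant uninformative.
    """
    informative = 0
    verdict = "segregates"
    for person in pedigree:
        gt = variant.genotype(person.sample_id)
        if not person.genotyped or gt == "./.":
            continue
        informative += 1
        if person.carries_disease_haplotype:
            if gt not in ("0/1", "1/1"):
                verdict = "violates"
        else:
            if gt != "0/0":
                verdict = "violates"
    if informative < 2:
        return "uninformative"
    return verdict


def _is_rare(variant: VariantRecord, config: FilterConfig) -> bool:
    """Rare means MAF < threshold in EVERY configured panel; novel counts as rare."""
    panels = config.panels if config.panels is not None else list(variant.panel_freqs)
    for panel in panels:
        maf = variant.panel_freqs.get(panel, 0.0)  # absent from panel: novel
        if maf >= config.maf_threshold:
            return False
    return True


def _shared_het(variant: VariantRecord, config: FilterConfig) -> bool:
    for s in config.sequenced_affecteds:
        gt = variant.genotype(s)
        if gt == "./.":
            if config.missing_fails_sharing:
                return False
            continue
        if gt != "0/1":
            return False
    return True


def _absent_from_controls(variant: VariantRecord, config: FilterConfig) -> bool:
    for s in config.control_samples:
        gt = variant.genotype(s)
        if gt == "./.":
            if config.missing_passes_control:
                continue
            return False
        if gt != "0/0":
            return False
    return True


def run_filter_cascade(
    variants: Sequence[VariantRecord],
    config: FilterConfig,
    pedigree: Optional[Sequence[PedigreeSample]] = None,
) -> FilterReport:
    """Apply the fixed-order cascade and record per-stage accounting.

    The segregation stage is applied only when a pedigree is supplied (it
    keeps variants classified "segregates"). Unknown configured samples
    raise a configuration error.
    """
    known = set()
    for v in variants:
        known.update(v.genotypes)
    if variants:
        for s in config.sequenced_affecteds + config.control_samples:
            if s not in known:
                raise ValidationError(f"configured sample {s!r} not in genotype columns")

    current = list(variants)
    report = FilterReport()

    def stage(name: str, keep) -> None:
        nonlocal current
        after = [v for v in current if keep(v)]
        report.record(name, current, after)
        current = after

    stage("quality", lambda v: v.quality >= config.min_quality)
    stage("rarity", lambda v: _is_rare(v, config))
    stage("zygosity", lambda v: all(
        variant_gt in ("0/1", "./.")
        for variant_gt in (v.genotype(s) for s in config.sequenced_affecteds)
    ))
    stage("sharing", lambda v: _shared_het(v, config))
    if config.locus is not None:
        stage("locus", lambda v: config.locus.contains(v.pos - 1))
    if pedigree is not None:
        stage("segregation",
              lambda v: check_segregation(v, pedigree) == "segregates")
    stage("control_absence", lambda v: _absent_from_controls(v, config))
    return report
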