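"""End-to-end orchestration of the discovery scenario.

The demo scenario scales the real discovery down to desk size: a ~1 Mb
chromosome carrying a pair of inverted 98%-identity low-copy repeats, a
~400 kb NAHR-mediated inversion with breakpoints inside the repeats, a 30x
FR paired-end library and ~6x long reads, a three-generation dominant
family with a disease-haplotype variant cascade, and a rare-variant
case/control burden cohort. Every stage runs against recorded ground truth
and the bundle includes a machine-readable truth-comparison summary.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import seq_io
from .assoc_stats import permutation_burden
from .inversion_long import call_from_long_reads, reconcile_evidence
from .inversion_short import call_from_pairs
from .lcr_finder import find_inverted_repeats, flag_nahr_susceptible
from .model import InsertProfile, Interval, ValidationError
from .prioritize import FilterConfig, run_filter_cascade
from .synthetic_data import (
    SEQUENCED_AFFECTEDS,
    apply_inversion,
    default_pedigree,
    derive_seed,
    generate_genome,
    long_read_count_for_coverage,
    nahr_inversion_bounds,
    plant_inverted_lcr,
    simulate_case_control_genotypes,
    simulate_family_variants,
    simulate_long_read_alignments,
    simulate_paired_end_alignments,
)

log = logging.getLogger("invscout")


@dataclass
class ScenarioConfig:
    """Single structured configuration driving the full demo pipeline."""

    seed: int
    genome_length_bp: int = 1_000_000
    gc_fraction: float = 0.42
    chrom: str = "chrS"
    # inverted LCR pair (NAHR substrate)
    lcr_copy_len_bp: int = 20_000
    lcr_separation_bp: int = 360_000
    lcr_identity_pct: float = 98.0
    lcr_anchor_bp: int = 290_000
    # inversion; None bounds = NAHR breakpoints drawn inside the LCR copies
    inversion_enabled: bool = True
    inversion_start: Optional[int] = None
    inversion_end: Optional[int] = None
    # libraries
    short_coverage_x: float = 30.0
    insert_mean_bp: float = 350.0
    insert_sd_bp: float = 35.0
    read_len_bp: int = 100
    long_coverage_x: float = 6.0
    long_read_len_bp: int = 20_000
    # callers
    min_support_short: int = 3
    k_spread: float = 5.0
    min_support_long: int = 2
    # family scenario
    locus_start: int = 250_000
    locus_end: int = 750_000
    n_linked_unique: int = 4
    n_linked_shared: int = 34
    n_linked_noncoseg: int = 41
    n_offlocus: int = 100
    n_control_samples: int = 50
    # association scenario
    n_cases: int = 558
    n_controls: int = 755
    region_bp: int = 3545
    causal_pct: float = 40.0
    protective_pct: float = 10.0
    max_or: float = 5.0
    n_perm: int = 2000

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValidationError(f"unknown config keys: {sorted(bad)}")
        if "seed" not in raw:
            raise ValidationError("config must set a seed")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def build_truth(config: ScenarioConfig):
    """Reference, donor and ground truth for a scenario."""
    rng = np.random.default_rng(derive_seed(config.seed, "genome"))
    ref = generate_genome(config.genome_length_bp, config.gc_fraction,
                          seed=derive_seed(config.seed, "genome"),
                          name=config.chrom)
    ref = plant_inverted_lcr(
        ref, config.lcr_copy_len_bp, config.lcr_separation_bp,
        identity_pct=config.lcr_identity_pct, anchor_bp=config.lcr_anchor_bp,
        seed=derive_seed(config.seed, "lcr"),
    )
    donor = ref
    if config.inversion_enabled:
        if config.inversion_start is not None and config.inversion_end is not None:
            start, end = config.inversion_start, config.inversion_end
            mech = "arbitrary"
        else:
            start, end = nahr_inversion_bounds(ref.lcr_pairs[0], rng)
            mech = "nahr"
        donor = apply_inversion(ref, start, end, mechanism=mech)
    return ref, donor


def run_end_to_end(config: ScenarioConfig, out_dir: Optional[Path] = None) -> dict:
    """Execute simulate → call-short → call-long → reconcile → find-lcrs →
    filter → associate, and compare every result with the planted truth.

    Returns a bundle dict; if ``out_dir`` is given, also writes FASTA/SAM/BED/
    VCF/TSV artifacts and a JSON truth summary there.
    """
    log.info("scenario seed=%d genome=%d bp", config.seed, config.genome_length_bp)
    ref, donor = build_truth(config)
    truth_inv = donor.inversions[0] if donor.inversions else None

    profile = InsertProfile(mean_bp=config.insert_mean_bp, sd_bp=config.insert_sd_bp,
                            read_len_bp=config.read_len_bp)
    pairs = simulate_paired_end_alignments(
        ref, donor, config.short_coverage_x, profile,
        seed=derive_seed(config.seed, "short_reads"),
    )
    short_calls = call_from_pairs(pairs, min_support=config.min_support_short,
                                  k_spread=config.k_spread)
    log.info("short-read stage: %d pairs, %d call(s)", len(pairs), len(short_calls))

    n_long = long_read_count_for_coverage(
        len(ref), config.long_coverage_x, config.long_read_len_bp
    )
    long_reads = simulate_long_read_alignments(
        ref, donor, n_long, ("constant", config.long_read_len_bp),
        seed=derive_seed(config.seed, "long_reads"),
    )
    long_calls = call_from_long_reads(long_reads, min_support=config.min_support_long)
    log.info("long-read stage: %d reads, %d call(s)", n_long, len(long_calls))

    calls = reconcile_evidence(short_calls, long_calls)

    hits = find_inverted_repeats(ref.sequence)
    nahr_hits = flag_nahr_susceptible(
        hits, min_len_bp=1000, min_identity_pct=98.0,
        min_sep_bp=config.lcr_separation_bp // 4,
        max_sep_bp=4 * config.lcr_separation_bp,
    )
    log.info("lcr stage: %d hit(s), %d NAHR-susceptible", len(hits), len(nahr_hits))

    pedigree = default_pedigree()
    locus = Interval(config.locus_start, config.locus_end)
    variants, var_truth = simulate_family_variants(
        pedigree, locus,
        n_linked_unique=config.n_linked_unique,
        n_linked_shared_polymorphic=config.n_linked_shared,
        n_offlocus=config.n_offlocus,
        n_linked_noncosegregating=config.n_linked_noncoseg,
        n_control_samples=config.n_control_samples,
        seed=derive_seed(config.seed, "family"),
        chrom=config.chrom, chrom_len=config.genome_length_bp,
    )
    ctrl_ids = sorted({s for v in variants for s in v.genotypes if s.startswith("CTRL")})
    fconfig = FilterConfig(sequenced_affecteds=list(SEQUENCED_AFFECTEDS),
                           locus=locus, control_samples=ctrl_ids)
    report = run_filter_cascade(variants, fconfig, pedigree=pedigree)
    log.info("filter stage: %s", report.as_rows())

    G, y, info = simulate_case_control_genotypes(
        config.n_cases, config.n_controls, region_bp=config.region_bp,
        causal_pct=config.causal_pct, protective_pct=config.protective_pct,
        max_or=config.max_or, seed=derive_seed(config.seed, "cohort"),
    )
    burden = permutation_burden(G, y, n_perm=config.n_perm,
                                seed=derive_seed(config.seed, "burden"))
    log.info("association stage: statistic=%.3f p=%.4g", burden.statistic,
             burden.p_value)

    summary = _truth_summary(config, ref, donor, calls, hits, report,
                             var_truth, burden)
    bundle = {
        "config": config,
        "reference": ref,
        "donor": donor,
        "pairs": pairs,
        "long_reads": long_reads,
        "short_calls": short_calls,
        "long_calls": long_calls,
        "calls": calls,
        "lcr_hits": hits,
        "nahr_hits": nahr_hits,
        "pedigree": pedigree,
        "variants": variants,
        "variant_truth": var_truth,
        "filter_report": report,
        "burden": burden,
        "summary": summary,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _truth_summary(config, ref, donor, calls, lcr_hits, report, var_truth,
                   burden) -> dict:
    summary: dict = {"seed": config.seed}
    if donor.inversions:
        inv = donor.inversions[0]
        recovered = [c for c in calls if c.contains_truth(inv.start, inv.end)]
        best = recovered[0] if recovered else None
        summary["inversion"] = {
            "truth": [inv.start, inv.end],
            "n_calls": len(calls),
            "recovered": bool(recovered),
            "evidence": best.evidence if best else None,
            "prox_interval": [best.proximal.start, best.proximal.end] if best else None,
            "dist_interval": [best.distal.start, best.distal.end] if best else None,
            "prox_midpoint_error_bp": (
                abs((best.proximal.start + best.proximal.end) // 2 - inv.start)
                if best else None
            ),
            "dist_midpoint_error_bp": (
                abs((best.distal.start + best.distal.end) // 2 - inv.end)
                if best else None
            ),
        }
    else:
        summary["inversion"] = {"truth": None, "n_calls": len(calls),
                                "recovered": None}
    if ref.lcr_pairs:
        pair = ref.lcr_pairs[0]
        match = [
            h for h in lcr_hits
            if abs(h.interval_a.start - pair.copy_a.start) <= 100
            and abs(h.interval_b.end - pair.copy_b.end) <= 100
        ]
        summary["lcr"] = {
            "truth_identity_pct": pair.identity_pct,
            "recovered": bool(match),
            "identity_pct": match[0].identity_pct if match else None,
        }
    expected = {
        "locus": config.n_linked_unique + config.n_linked_shared
        + config.n_linked_noncoseg,
        "segregation": config.n_linked_unique + config.n_linked_shared,
        "control_absence": config.n_linked_unique,
    }
    summary["filter"] = {
        "stages": report.as_rows(),
        "expected_key_counts": expected,
        "matches_truth": all(report.n_out[k] == v for k, v in expected.items()),
    }
    summary["association"] = {
        "statistic": burden.statistic,
        "p_value": burden.p_value,
        "n_variants": burden.n_variants,
    }
    return summary


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config: ScenarioConfig = bundle["config"]
    ref, donor = bundle["reference"], bundle["donor"]
    seq_io.write_fasta({ref.name: ref.sequence}, out_dir / "reference.fasta")
    seq_io.write_fasta({donor.name + "_donor": donor.sequence},
                       out_dir / "donor.fasta")
    ref_lengths = {ref.name: len(ref)}
    seq_io.write_sam_pairs(bundle["pairs"], out_dir / "short_reads.sam", ref_lengths)
    seq_io.write_sam_long(bundle["long_reads"], out_dir / "long_reads.sam",
                          ref_lengths)
    truth_rows = []
    for i, pair in enumerate(ref.lcr_pairs):
        truth_rows.append((ref.name, pair.copy_a.start, pair.copy_a.end, f"lcr{i}_a"))
        truth_rows.append((ref.name, pair.copy_b.start, pair.copy_b.end, f"lcr{i}_b"))
    for i, inv in enumerate(donor.inversions):
        truth_rows.append((ref.name, inv.start, inv.end, f"inversion{i}"))
    seq_io.write_bed(truth_rows, out_dir / "truth.bed")
    seq_io.write_calls_tsv(bundle["calls"], out_dir / "calls.tsv")
    seq_io.write_bed(
        [
            (ref.name, h.interval_a.start, h.interval_a.end, f"hit{i}_a")
            for i, h in enumerate(bundle["lcr_hits"])
        ]
        + [
            (ref.name, h.interval_b.start, h.interval_b.end, f"hit{i}_b")
            for i, h in enumerate(bundle["lcr_hits"])
        ],
        out_dir / "lcr_hits.bed",
    )
    seq_io.write_variant_table(bundle["variants"], out_dir / "family_variants.vcf")
    seq_io.write_pedigree_tsv(bundle["pedigree"], out_dir / "pedigree.tsv")
    with open(out_dir / "filter_report.tsv", "w") as fh:
        fh.write("stage\tn_in\tn_out\n")
        for stage, n_in, n_out in bundle["filter_report"].as_rows():
            fh.write(f"{stage}\t{n_in}\t{n_out}\n")
    burden = bundle["burden"]
    with open(out_dir / "association.tsv", "w") as fh:
        fh.write("test\tstatistic\tp_value\tn_variants\tn_perm\n")
        fh.write(
            f"permutation_burden\t{burden.statistic:.6f}\t{burden.p_value:.6g}\t"
            f"{burden.n_variants}\t{burden.n_perm}\n"
        )
    with open(out_dir / "truth_summary.json", "w") as fh:
        json.dump(bundle["summary"], fh, indent=2)
    config.to_yaml(out_dir / "scenario.yaml")
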