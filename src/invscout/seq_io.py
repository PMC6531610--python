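"""Readers and writers for the interchange formats the pipeline touches.

Dialects are deliberately minimal but strict:

* FASTA via Biopython, with duplicate-name and alphabet validation and
  uppercase normalization on read.
* SAM restricted to the 11 mandatory columns plus the ``SA`` tag for split
  long reads; CIGAR uses only M/S. Parsing goes through pysam.
* Variant tables are a tab-separated minimal VCF: single ALT per row,
  ``GT``-only FORMAT, panel frequencies as ``AF_<panel>`` INFO keys.
* BED3+name for ground-truth intervals.

All writer/reader compositions are identities on valid data; malformed
records raise instead of being coerced.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AlignedPair,
    AlignmentSegment,
    LongReadAlignment,
    ValidationError,
    VariantRecord,
)

IUPAC_NT = set("ACGTUNRYKMSWBDHV")

FLAG_PAIRED = 0x1
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SUPPLEMENTARY = 0x800


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered name -> uppercase sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ParseError(f"non-IUPAC characters in {rec.id!r}: {sorted(bad)}")
        out[rec.id] = seq
    return out


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# SAM: paired-end


def _sam_header(ref_lengths: dict[str, int]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, ln in ref_lengths.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{ln}")
    return "\n".join(lines) + "\n"


def write_sam_pairs(pairs: Iterable[AlignedPair], path, ref_lengths: dict[str, int]) -> None:
    """Write pairs as minimal SAM; TLEN is positive on the leftmost read."""
    with open(path, "w") as fh:
        fh.write(_sam_header(ref_lengths))
        for p in pairs:
            cigar = f"{p.read_len_bp}M"
            tags = "\tbs:i:1" if p.spanning_flag else ""
            for mate, pos, strand, mpos, mstrand in (
                (FLAG_FIRST, p.pos1, p.strand1, p.pos2, p.strand2),
                (FLAG_SECOND, p.pos2, p.strand2, p.pos1, p.strand1),
            ):
                flag = FLAG_PAIRED | mate
                if strand == "-":
                    flag |= FLAG_REVERSE
                if mstrand == "-":
                    flag |= FLAG_MATE_REVERSE
                tlen = p.template_len_bp if pos <= mpos else -abs(p.template_len_bp)
                if pos == mpos:  # same start: keep the stored sign on mate 1
                    tlen = p.template_len_bp if mate == FLAG_FIRST else -p.template_len_bp
                fh.write(
                    f"{p.pair_id}\t{flag}\t{p.chrom}\t{pos}\t{p.mapq}\t{cigar}\t=\t"
                    f"{mpos}\t{tlen}\t*\t*{tags}\n"
                )


def read_sam_pairs(path) -> list[AlignedPair]:
    """Reconstruct pairs by QNAME mate-joining; unmated reads warn and are dropped."""
    mates: dict[str, dict[int, pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        for rec in sam:
            if rec.flag & FLAG_SUPPLEMENTARY:
                continue
            which = rec.flag & (FLAG_FIRST | FLAG_SECOND)
            mates.setdefault(rec.query_name, {})[which] = rec
    pairs: list[AlignedPair] = []
    unmated = []
    for qname, d in mates.items():
        if FLAG_FIRST not in d or FLAG_SECOND not in d:
            unmated.append(qname)
            continue
        r1, r2 = d[FLAG_FIRST], d[FLAG_SECOND]
        rl = r1.infer_query_length() or (r1.reference_length or 0)
        pairs.append(
            AlignedPair(
                pair_id=qname,
                chrom=r1.reference_name,
                pos1=r1.reference_start + 1,
                strand1="-" if r1.is_reverse else "+",
                pos2=r2.reference_start + 1,
                strand2="-" if r2.is_reverse else "+",
                read_len_bp=rl,
                template_len_bp=r1.template_length,
                mapq=min(r1.mapping_quality, r2.mapping_quality),
                spanning_flag=bool(r1.has_tag("bs") or r2.has_tag("bs")),
            )
        )
    if unmated:
        warnings.warn(f"excluded {len(unmated)} unmated read(s): {unmated[:5]}")
    return pairs


# ---------------------------------------------------------------------------
# SAM: split long reads


def _segment_cigar(seg: AlignmentSegment, read_len: int) -> str:
    m = seg.read_end - seg.read_start
    if seg.strand == "+":
        lead, trail = seg.read_start, read_len - seg.read_end
    else:  # stored sequence is reverse-complemented, clips swap ends
        lead, trail = read_len - seg.read_end, seg.read_start
    parts = []
    if lead:
        parts.append(f"{lead}S")
    parts.append(f"{m}M")
    if trail:
        parts.append(f"{trail}S")
    return "".join(parts)


def write_sam_long(reads: Iterable[LongReadAlignment], path,
                   ref_lengths: dict[str, int]) -> None:
    """One SAM line per segment; the first is primary, the rest supplementary."""
    with open(path, "w") as fh:
        fh.write(_sam_header(ref_lengths))
        for read in reads:
            sa_parts = [
                f"{read.chrom},{s.ref_start + 1},{'-' if s.strand == '-' else '+'},"
                f"{_segment_cigar(s, read.read_len_bp)},60,0;"
                for s in read.segments
            ]
            for i, seg in enumerate(read.segments):
                flag = 0 if i == 0 else FLAG_SUPPLEMENTARY
                if seg.strand == "-":
                    flag |= FLAG_REVERSE
                sa = "".join(sa_parts[:i] + sa_parts[i + 1 :])
                tags = f"\tSA:Z:{sa}" if sa else ""
                fh.write(
                    f"{read.read_id}\t{flag}\t{read.chrom}\t{seg.ref_start + 1}\t60\t"
                    f"{_segment_cigar(seg, read.read_len_bp)}\t*\t0\t0\t*\t*{tags}\n"
                )


def read_sam_long(path) -> list[LongReadAlignment]:
    """Rebuild segmented long-read alignments from primary+supplementary lines."""
    grouped: dict[str, list] = {}
    chroms: dict[str, str] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        for rec in sam:
            cig = rec.cigartuples or []
            lead = cig[0][1] if cig and cig[0][0] == 4 else 0
            trail = cig[-1][1] if len(cig) > (1 if lead else 0) and cig[-1][0] == 4 else 0
            m = sum(ln for op, ln in cig if op == 0)
            read_len = lead + m + trail
            if rec.is_reverse:
                read_start = trail
            else:
                read_start = lead
            seg = AlignmentSegment(
                read_start=read_start,
                read_end=read_start + m,
                ref_start=rec.reference_start,
                ref_end=rec.reference_start + m,
                strand="-" if rec.is_reverse else "+",
            )
            grouped.setdefault(rec.query_name, []).append((seg, read_len))
            chroms[rec.query_name] = rec.reference_name
    out = []
    for rid, segs in grouped.items():
        read_len = max(rl for _, rl in segs)
        ordered = sorted((s for s, _ in segs), key=lambda s: s.read_start)
        out.append(
            LongReadAlignment(read_id=rid, chrom=chroms[rid], segments=ordered,
                              read_len_bp=read_len)
        )
    out.sort(key=lambda r: r.read_id)
    return out


# ---------------------------------------------------------------------------
# minimal VCF


VCF_COLUMNS = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]


def write_variant_table(variants: Sequence[VariantRecord], path,
                        samples: Sequence[str] | None = None) -> None:
    """Write a tab-separated minimal VCF (single ALT, GT-only FORMAT)."""
    if samples is None:
        seen: dict[str, None] = {}
        for v in variants:
            for s in v.genotypes:
                seen.setdefault(s)
        samples = list(seen)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=invscout\n")
        fh.write("\t".join(VCF_COLUMNS + list(samples)) + "\n")
        for v in variants:
            info_parts = [f"AF_{panel}={maf!r}" for panel, maf in v.panel_freqs.items()]
            info_parts += [f"{k}={val}" for k, val in v.annotations.items()]
            info = ";".join(info_parts) if info_parts else "."
            row = [
                v.chrom, str(v.pos), v.var_id, v.ref_allele, v.alt_allele,
                f"{v.quality:g}", "PASS", info, "GT",
            ] + [v.genotype(s) for s in samples]
            fh.write("\t".join(row) + "\n")


def read_variant_table(path) -> list[VariantRecord]:
    samples: list[str] = []
    out: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if cols[:9] != VCF_COLUMNS:
                    raise ParseError(f"unexpected header columns: {cols[:9]}")
                samples = cols[9:]
                continue
            fields = line.split("\t")
            if not samples:
                raise ParseError("data line before #CHROM header")
            if len(fields) != 9 + len(samples):
                raise ParseError(
                    f"line {lineno}: {len(fields)} columns, expected {9 + len(samples)}"
                )
            chrom, pos, vid, ref, alt, qual, _filt, info, fmt = fields[:9]
            if fmt.split(":")[0] != "GT":
                raise ParseError(f"line {lineno}: FORMAT must lead with GT")
            panel_freqs: dict[str, float] = {}
            annotations: dict[str, str] = {}
            if info != ".":
                for item in info.split(";"):
                    if "=" not in item:
                        continue
                    k, val = item.split("=", 1)
                    if k.startswith("AF_"):
                        panel_freqs[k[3:]] = float(val)
                    else:
                        annotations[k] = val
            genotypes = {}
            for s, g in zip(samples, fields[9:]):
                gt = g.split(":")[0]
                if gt not in ("0/0", "0/1", "1/0", "1/1", "./."):
                    raise ParseError(f"line {lineno}: bad genotype {gt!r} for {s}")
                genotypes[s] = "0/1" if gt == "1/0" else gt
            out.append(
                VariantRecord(
                    chrom=chrom, pos=int(pos), ref_allele=ref, alt_allele=alt,
                    var_id=vid, quality=float(qual), panel_freqs=panel_freqs,
                    genotypes=genotypes, annotations=annotations,
                )
            )
    return out


# ---------------------------------------------------------------------------
# pedigree TSV


PED_COLUMNS = ["sample_id", "father", "mother", "generation", "affection",
               "carries_disease_haplotype", "genotyped", "aao_years", "aai_years"]


def write_pedigree_tsv(pedigree: Sequence["PedigreeSample"], path) -> None:
    from .model import PedigreeSample  # noqa: F401  (type reference)

    with open(path, "w") as fh:
        fh.write("\t".join(PED_COLUMNS) + "\n")
        for p in pedigree:
            fh.write(
                "\t".join(
                    [
                        p.sample_id, p.father or ".", p.mother or ".",
                        str(p.generation), p.affection,
                        "1" if p.carries_disease_haplotype else "0",
                        "1" if p.genotyped else "0",
                        "" if p.aao_years is None else f"{p.aao_years:g}",
                        "" if p.aai_years is None else f"{p.aai_years:g}",
                    ]
                )
                + "\n"
            )


def read_pedigree_tsv(path) -> list:
    from .model import PedigreeSample

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PED_COLUMNS:
            raise ParseError(f"unexpected pedigree columns: {header}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(PED_COLUMNS):
                raise ParseError(f"pedigree row has {len(f)} fields")
            out.append(
                PedigreeSample(
                    sample_id=f[0],
                    father=None if f[1] == "." else f[1],
                    mother=None if f[2] == "." else f[2],
                    generation=int(f[3]),
                    affection=f[4],
                    carries_disease_haplotype=f[5] == "1",
                    genotyped=f[6] == "1",
                    aao_years=float(f[7]) if f[7] else None,
                    aai_years=float(f[8]) if f[8] else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# inversion-call TSV


CALL_COLUMNS = ["chrom", "prox_start", "prox_end", "dist_start", "dist_end",
                "support_pp", "support_mm", "evidence", "one_sided"]


def write_calls_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.proximal.start}\t{c.proximal.end}\t"
                f"{c.distal.start}\t{c.distal.end}\t{c.support_pp}\t{c.support_mm}\t"
                f"{c.evidence}\t{int(c.one_sided)}\n"
            )


def read_calls_tsv(path) -> list:
    from .model import Interval, InversionCall

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CALL_COLUMNS:
            raise ParseError(f"unexpected call columns: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                InversionCall(
                    chrom=f[0],
                    proximal=Interval(int(f[1]), int(f[2])),
                    distal=Interval(int(f[3]), int(f[4])),
                    support_pp=int(f[5]), support_mm=int(f[6]),
                    evidence=f[7], one_sided=bool(int(f[8])),
                )
            )
    return out


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path) -> None:
    """Write BED3+name, sorted by (chrom, start, end)."""
    rows = []
    for chrom, start, end, name in intervals:
        if start < 0 or end <= start:
            raise ValidationError(f"bad BED interval {chrom}:{start}-{end}")
        rows.append((chrom, int(start), int(end), name))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else "."))
    return out
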