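"""Round-trip guarantees and strictness of the format layer."""
import warnings

import pytest

from invscout import seq_io
from invscout.model import (
    AlignedPair,
    AlignmentSegment,
    Interval,
    InversionCall,
    LongReadAlignment,
    ValidationError,
    VariantRecord,
)
from invscout.synthetic_data import default_pedigree


class TestFasta:
    def test_round_trip(self, tmp_path):
        records = {"chr1": "ACGTACGTAC" * 20, "chr2": "GGGGCCCCTT"}
        path = tmp_path / "x.fasta"
        seq_io.write_fasta(records, path)
        assert seq_io.read_fasta(path) == records

    def test_lowercase_uppercased_on_read(self, tmp_path):
        path = tmp_path / "lc.fasta"
        path.write_text(">r1\nacgtN\n")
        assert seq_io.read_fasta(path) == {"r1": "ACGTN"}

    def test_empty_file_gives_empty_mapping(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert seq_io.read_fasta(path) == {}

    def test_duplicate_names_raise(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(seq_io.ParseError):
            seq_io.read_fasta(path)

    def test_non_iupac_raises(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nACGT9\n")
        with pytest.raises(seq_io.ParseError):
            seq_io.read_fasta(path)


def _mk_pairs(n=10):
    out = []
    for i in range(n):
        pos1 = 100 + 500 * i
        out.append(
            AlignedPair(
                pair_id=f"p{i}", chrom="chrS", pos1=pos1, strand1="+",
                pos2=pos1 + 250, strand2="-", read_len_bp=100,
                template_len_bp=350, mapq=60, spanning_flag=(i == 0),
            )
        )
    return out


class TestSamPairs:
    def test_round_trip_preserves_strands_tlen_and_flags(self, tmp_path):
        pairs = _mk_pairs()
        path = tmp_path / "pairs.sam"
        seq_io.write_sam_pairs(pairs, path, {"chrS": 100_000})
        back = sorted(seq_io.read_sam_pairs(path), key=lambda p: p.pair_id)
        assert len(back) == 10
        for orig, rec in zip(sorted(pairs, key=lambda p: p.pair_id), back):
            assert (rec.pos1, rec.strand1, rec.pos2, rec.strand2) == (
                orig.pos1, orig.strand1, orig.pos2, orig.strand2
            )
            # SAM convention: leftmost read carries the positive TLEN
            assert rec.template_len_bp == orig.template_len_bp
            assert rec.spanning_flag == orig.spanning_flag

    def test_unmated_read_warns_and_is_excluded(self, tmp_path):
        path = tmp_path / "unmated.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrS\tLN:1000\n"
            "lonely\t65\tchrS\t100\t60\t50M\t=\t300\t250\t*\t*\n"
        )
        with pytest.warns(UserWarning, match="unmated"):
            pairs = seq_io.read_sam_pairs(path)
        assert pairs == []

    def test_malformed_flag_raises(self, tmp_path):
        path = tmp_path / "badflag.sam"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrS\tLN:1000\n"
            "r\tXYZ\tchrS\t100\t60\t50M\t=\t300\t250\t*\t*\n"
        )
        with pytest.raises(Exception):
            seq_io.read_sam_pairs(path)


class TestSamLong:
    def test_split_read_round_trip(self, tmp_path):
        read = LongReadAlignment(
            read_id="lr0", chrom="chrS", read_len_bp=5000,
            segments=[
                AlignmentSegment(0, 2000, 10_000, 12_000, "+"),
                AlignmentSegment(2000, 4000, 26_000, 28_000, "-"),
                AlignmentSegment(4000, 5000, 30_000, 31_000, "+"),
            ],
        )
        path = tmp_path / "long.sam"
        seq_io.write_sam_long([read], path, {"chrS": 100_000})
        (back,) = seq_io.read_sam_long(path)
        assert back.read_len_bp == 5000
        assert back.segments == read.segments


class TestVariantTable:
    def _records(self):
        return [
            VariantRecord(
                chrom="chrS", pos=100 + i, ref_allele="A", alt_allele="G",
                var_id=f"v{i}", quality=90.0,
                panel_freqs={"1KG": 0.004},
                genotypes={"s1": "0/1", "s2": "0/0", "s3": "./."},
            )
            for i in range(5)
        ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "v.vcf"
        recs = self._records()
        seq_io.write_variant_table(recs, path)
        assert seq_io.read_variant_table(path) == recs

    def test_missing_genotype_never_counts_as_carrier(self):
        v = self._records()[0]
        assert not v.is_carrier("s3")
        assert not v.is_carrier("unknown_sample")

    def test_info_panel_frequency_parsed(self, tmp_path):
        path = tmp_path / "af.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chrS\t42\t.\tA\tT\t99\tPASS\tAF_1KG=0.004\tGT\t0/1\n"
        )
        (rec,) = seq_io.read_variant_table(path)
        assert rec.panel_freqs == {"1KG": 0.004}

    def test_column_mismatch_raises(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "chrS\t42\t.\tA\tT\t99\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.raises(seq_io.ParseError):
            seq_io.read_variant_table(path)


class TestBedAndTables:
    def test_bed_written_sorted(self, tmp_path):
        path = tmp_path / "x.bed"
        seq_io.write_bed(
            [("chrS", 500, 900, "b"), ("chrS", 0, 100, "lcrA")], path
        )
        assert path.read_text().splitlines() == [
            "chrS\t0\t100\tlcrA", "chrS\t500\t900\tb"
        ]

    @pytest.mark.parametrize("interval", [("chrS", -1, 10, "x"), ("chrS", 10, 10, "x")])
    def test_bad_bed_interval_raises(self, tmp_path, interval):
        with pytest.raises(ValidationError):
            seq_io.write_bed([interval], tmp_path / "bad.bed")

    def test_pedigree_round_trip(self, tmp_path):
        ped = default_pedigree()
        path = tmp_path / "ped.tsv"
        seq_io.write_pedigree_tsv(ped, path)
        assert seq_io.read_pedigree_tsv(path) == ped

    def test_calls_round_trip(self, tmp_path):
        calls = [
            InversionCall(chrom="chrS", proximal=Interval(100, 500),
                          distal=Interval(5000, 5400), support_pp=7,
                          support_mm=6, evidence="both"),
        ]
        path = tmp_path / "calls.tsv"
        seq_io.write_calls_tsv(calls, path)
        assert seq_io.read_calls_tsv(path) == calls
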