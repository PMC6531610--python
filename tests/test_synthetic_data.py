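"""Generators: determinism, planted-feature fidelity, coordinate reflection,
Mendelian transmission and the case/control logistic model."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invscout.model import (
    InsertProfile,
    Interval,
    InversionEvent,
    SyntheticGenome,
    ValidationError,
    revcomp,
)
from invscout.synthetic_data import (
    SEQUENCED_AFFECTEDS,
    apply_inversion,
    default_pedigree,
    generate_genome,
    map_donor_interval,
    map_donor_point,
    plant_inverted_lcr,
    simulate_case_control_genotypes,
    simulate_family_variants,
    simulate_long_read_alignments,
    simulate_paired_end_alignments,
)


class TestGenerateGenome:
    def test_seed_determinism(self):
        a = generate_genome(10_000, 0.5, seed=7)
        b = generate_genome(10_000, 0.5, seed=7)
        assert a.sequence == b.sequence

    def test_gc_fraction_within_binomial_bound(self):
        n, gc = 50_000, 0.62
        g = generate_genome(n, gc, seed=3)
        observed = sum(g.sequence.count(b) for b in "GC")
        sd = np.sqrt(n * gc * (1 - gc))
        assert abs(observed - n * gc) <= 3 * sd

    @pytest.mark.parametrize("length,gc", [(100, 0.5), (5000, 0.0), (5000, 1.0)])
    def test_invalid_inputs_raise(self, length, gc):
        with pytest.raises(ValidationError):
            generate_genome(length, gc, seed=1)


class TestPlantInvertedLcr:
    def test_full_identity_is_exact_revcomp(self, small_genome):
        g = plant_inverted_lcr(small_genome, 2000, 3000, identity_pct=100.0,
                               anchor_bp=1000, seed=5)
        pair = g.lcr_pairs[0]
        a = g.sequence[pair.copy_a.start : pair.copy_a.end]
        b = g.sequence[pair.copy_b.start : pair.copy_b.end]
        assert b == revcomp(a)
        assert pair.identity_pct == 100.0

    def test_planted_identity_matches_hamming_count(self):
        g = generate_genome(50_000, 0.5, seed=9)
        g = plant_inverted_lcr(g, 5000, 10_000, identity_pct=98.0,
                               anchor_bp=2000, seed=10)
        pair = g.lcr_pairs[0]
        a = g.sequence[pair.copy_a.start : pair.copy_a.end]
        b = g.sequence[pair.copy_b.start : pair.copy_b.end]
        hamming_identity = 100.0 * sum(
            x == y for x, y in zip(a, revcomp(b))
        ) / len(a)
        assert 97.5 <= hamming_identity <= 98.5
        assert abs(pair.identity_pct - 98.0) <= 0.5

    def test_overflow_raises(self, small_genome):
        with pytest.raises(ValidationError):
            plant_inverted_lcr(small_genome, 4000, 5000, anchor_bp=0, seed=1)


class TestApplyInversion:
    def test_involution(self, small_genome):
        once = apply_inversion(small_genome, 2000, 6000)
        twice = apply_inversion(once, 2000, 6000)
        assert twice.sequence == small_genome.sequence
        assert len(twice.inversions) == 2

    def test_palindromic_segment_unchanged(self):
        g = SyntheticGenome(name="t", sequence="AACCGGTT")
        inv = apply_inversion(g, 2, 6)
        assert inv.sequence == "AACCGGTT"  # CCGG is its own revcomp
        g4 = SyntheticGenome(name="t", sequence="ACGT")
        assert apply_inversion(g4, 0, 4).sequence == "ACGT"

    def test_inverted_bounds_raise(self, small_genome):
        with pytest.raises(ValidationError):
            apply_inversion(small_genome, 6000, 2000)


class TestCoordinateReflection:
    EVENTS = [InversionEvent(3000, 7000)]

    def test_point_mirror(self):
        assert map_donor_point(3000, self.EVENTS) == (6999, True)
        assert map_donor_point(6999, self.EVENTS) == (3000, True)
        assert map_donor_point(100, self.EVENTS) == (100, False)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(min_value=0, max_value=9999))
    def test_reflection_is_an_involution(self, pos):
        mapped, flip1 = map_donor_point(pos, self.EVENTS)
        back, flip2 = map_donor_point(mapped, self.EVENTS)
        assert back == pos and flip1 == flip2

    def test_interval_mapping(self):
        # wholly inside: mirrored about the inversion, flipped
        assert map_donor_interval(3200, 3300, self.EVENTS) == (6700, 6800, True)
        # wholly outside: unchanged
        assert map_donor_interval(100, 200, self.EVENTS) == (100, 200, False)
        # straddling a breakpoint: must be split first
        assert map_donor_interval(2950, 3050, self.EVENTS) is None


class TestPairedEnd:
    def test_identity_donor_is_concordant_fr(self, small_genome, profile):
        pairs = simulate_paired_end_alignments(
            small_genome, small_genome, 30.0, profile, seed=2
        )
        expected_n = round(30.0 * len(small_genome) / (2 * profile.read_len_bp))
        assert len(pairs) == expected_n
        assert all(p.strand1 != p.strand2 for p in pairs)
        assert not any(p.spanning_flag for p in pairs)
        tlens = np.abs([p.template_len_bp for p in pairs])
        # location check: sample median close to the library mean
        assert abs(np.median(tlens) - 350.0) <= 3 * 35.0 / np.sqrt(len(pairs)) + 1

    def test_breakpoint_straddling_fragments_become_same_strand(
        self, inverted_scenario, profile
    ):
        ref, donor = inverted_scenario
        pairs = simulate_paired_end_alignments(ref, donor, 20.0, profile, seed=4)
        inv = donor.inversions[0]
        # pairs with exactly one read reflected show the ++/-- signature
        oddballs = [p for p in pairs if p.strand1 == p.strand2 and not p.spanning_flag]
        assert len(oddballs) > 10
        for p in oddballs:
            assert p.orientation_class in ("++", "--")
            # one mate near each breakpoint, mirrored across the inversion
            left, right = sorted([p.pos1 - 1, p.pos2 - 1])
            assert abs(left - inv.start) < 600 and abs(right - inv.end) < 600

    def test_hand_placed_fragment_reflection(self, inverted_scenario):
        ref, donor = inverted_scenario
        inv = donor.inversions[0]  # [30000, 70000)
        # read 2 of a fragment straddling the proximal breakpoint lands inside
        # the inversion: its reverse orientation flips to '+', mirrored distally
        mapped = map_donor_interval(30_200, 30_300, donor.inversions)
        assert mapped == (inv.start + inv.end - 30_300,
                          inv.start + inv.end - 30_200, True)

    def test_length_mismatch_raises(self, small_genome, profile):
        other = generate_genome(12_000, 0.5, seed=1)
        with pytest.raises(ValidationError):
            simulate_paired_end_alignments(small_genome, other, 10.0, profile, seed=0)


class TestLongReads:
    def test_no_inversion_single_plus_segment(self, small_genome):
        reads = simulate_long_read_alignments(
            small_genome, small_genome, 20, ("constant", 2000), seed=3
        )
        assert all(len(r.segments) == 1 and r.segments[0].strand == "+"
                   for r in reads)

    def test_read_spanning_inversion_has_three_alternating_segments(
        self, inverted_scenario
    ):
        ref, donor = inverted_scenario
        inv = donor.inversions[0]
        reads = simulate_long_read_alignments(ref, donor, 200,
                                              ("constant", 60_000), seed=6)
        spanning = [
            r for r in reads
            if r.segments[0].ref_start < inv.start
            and any(s.ref_end > inv.end for s in r.segments)
            and len(r.segments) == 3
        ]
        assert spanning, "no fully spanning reads simulated"
        for r in spanning:
            assert [s.strand for s in r.segments] == ["+", "-", "+"]
            mid = r.segments[1]
            assert (mid.ref_start, mid.ref_end) == (inv.start, inv.end)

    def test_read_inside_inversion_is_single_minus_segment(self, inverted_scenario):
        ref, donor = inverted_scenario
        reads = simulate_long_read_alignments(ref, donor, 300,
                                              ("constant", 2000), seed=7)
        inv = donor.inversions[0]
        inside = [
            r for r in reads if len(r.segments) == 1
            and inv.start <= r.segments[0].ref_start
            and r.segments[0].ref_end <= inv.end
        ]
        assert inside
        assert all(r.segments[0].strand == "-" for r in inside)

    def test_bad_read_count_raises(self, small_genome):
        with pytest.raises(ValidationError):
            simulate_long_read_alignments(small_genome, small_genome, 0, seed=1)


class TestFamilyVariants:
    LOCUS = Interval(250_000, 750_000)

    def test_unique_variants_track_the_disease_haplotype(self):
        ped = default_pedigree()
        variants, truth = simulate_family_variants(
            ped, self.LOCUS, n_linked_unique=4, n_linked_shared_polymorphic=0,
            n_offlocus=0, n_linked_noncosegregating=0, seed=13,
        )
        assert len(variants) == 4
        carriers = {p.sample_id for p in ped
                    if p.carries_disease_haplotype and p.genotyped}
        non_carriers = {p.sample_id for p in ped
                        if not p.carries_disease_haplotype and p.genotyped}
        for v in variants:
            assert truth[v.var_id] == "linked_unique"
            assert all(v.is_carrier(s) for s in carriers)
            assert not any(v.is_carrier(s) for s in non_carriers)
            # panel MAF 0 variants never appear in simulated controls
            assert not any(v.is_carrier(s) for s in v.genotypes if s.startswith("CTRL"))

    def test_mendelian_transmission_of_offlocus_variants(self):
        ped = default_pedigree()
        by_id = {p.sample_id: p for p in ped}
        variants, truth = simulate_family_variants(
            ped, self.LOCUS, n_linked_unique=0, n_linked_shared_polymorphic=0,
            n_offlocus=150, n_linked_noncosegregating=0, seed=17,
            panel_maf_law=("fixed", 0.3),  # common enough to exercise transmission
        )
        checked = 0
        for v in variants:
            for p in ped:
                if p.father not in by_id or p.mother not in by_id:
                    continue
                gts = (v.genotype(p.father), v.genotype(p.mother),
                       v.genotype(p.sample_id))
                if "./." in gts:
                    continue
                checked += 1
                fa, mo, kid = gts
                if kid != "0/0":  # child alt allele must come from a parent
                    assert fa != "0/0" or mo != "0/0"
                if kid == "1/1":  # one alt from each parent
                    assert fa != "0/0" and mo != "0/0"
                if fa == "1/1" and mo == "1/1":
                    assert kid == "1/1"
        assert checked > 100

    def test_empty_pedigree_raises(self):
        with pytest.raises(ValidationError):
            simulate_family_variants([], self.LOCUS, seed=1)


class TestCaseControl:
    def test_null_model_has_no_carrier_enrichment(self):
        G, y, _ = simulate_case_control_genotypes(
            2000, 2000, causal_pct=0.0, protective_pct=0.0, max_or=1.0001,
            seed=19, maf_law=("fixed", 0.005),
        )
        case_rate = G[y == 1].mean()
        ctrl_rate = G[y == 0].mean()
        se = np.sqrt(2 * 0.005 * 0.995 * 2 / (2000 * G.shape[1]))
        assert abs(case_rate - ctrl_rate) < 4 * se

    def test_single_causal_variant_recovers_assigned_odds_ratio(self):
        # one causal variant pinned at OR 5; a large cohort estimates it back
        G, y, info = simulate_case_control_genotypes(
            50_000, 50_000, causal_pct=100.0, protective_pct=0.0, max_or=5.0,
            n_variants=1, maf_law=("fixed", 0.005), seed=23,
        )
        a = G[y == 1].sum()
        c = G[y == 0].sum()
        b = 2 * 50_000 - a
        d = 2 * 50_000 - c
        or_hat = (a * d) / (b * c)
        assert info["beta"][0] == pytest.approx(np.log(5.0))
        assert abs(or_hat - 5.0) / 5.0 < 0.10

    def test_percentage_overflow_raises(self):
        with pytest.raises(ValidationError):
            simulate_case_control_genotypes(10, 10, causal_pct=80,
                                            protective_pct=30, seed=1)
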