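import numpy as np
import pytest

from conftest import random_dna
from helitronkit.annotate import (
    annotate_element,
    check_at_junction,
    delineate_acquired,
    detect_termini,
    detect_tsd,
    find_hairpin,
    refine_boundaries,
)
from helitronkit.search import CandidateHit, find_candidates
from helitronkit.seqcore import Interval, NucleotideSequence, reverse_complement
from helitronkit.synthetic import make_element
from oracles import best_inverted_repeat


class TestDetectTermini:
    @pytest.mark.parametrize(
        "element,expected",
        [
            ("TC" + "A" * 30 + "CTGC", (True, True)),
            ("TC" + "A" * 30 + "CTTA", (True, False)),
            ("GC" + "A" * 30 + "CTAT", (False, True)),
        ],
    )
    def test_examples(self, element, expected):
        assert detect_termini(element) == expected

    def test_too_short(self):
        with pytest.raises(ValueError):
            detect_termini("TCCT")


class TestAtJunction:
    @pytest.mark.parametrize(
        "up,down,expected",
        [("GGA", "TCC", True), ("GGC", "TCC", False), ("GGA", "ACC", False)],
    )
    def test_examples(self, up, down, expected):
        assert check_at_junction(up, down) is expected

    def test_empty_flank_rejected(self):
        with pytest.raises(ValueError):
            check_at_junction("", "TCC")


class TestDetectTsd:
    def test_duplicated_hexamer_found(self):
        up = "GGGGGGGGGGTTAACG"
        down = "TTAACGGGGGGGGGGG"
        found, kmer = detect_tsd(up, down)
        assert found and kmer == "TTAACG"

    def test_independent_flanks_not_duplicated(self):
        rng = np.random.default_rng(7)
        up, down = random_dna(rng, 20), random_dna(rng, 20)
        found, _ = detect_tsd(up, down)
        assert not found

    def test_short_duplication_below_k_min_ignored(self):
        up = "GGGGGGGGGGGGGACG"
        down = "ACGGGGGGGGGGGGGG"
        found, _ = detect_tsd(up, down, k_min=4, k_max=10)
        assert not found

    def test_short_flanks_warn(self):
        with pytest.warns(UserWarning, match="k_max"):
            detect_tsd("TTAACG", "TTAACG")


class TestFindHairpin:
    def test_constructed_perfect_hairpin(self):
        stem = "GCATGCAT"
        region = "T" * 20 + stem + "AAAA" + reverse_complement(stem) + "ACGTTACG"
        element = "C" * 60 + region
        hp = find_hairpin(element)
        # the planted stem (possibly extended by chance pairings under the
        # longest-arm-first ranking) must be found, matching the oracle
        arm, mism, right_end, start, loop = best_inverted_repeat(element[-50:])
        assert hp is not None
        assert (hp.arm_len, hp.mismatches) == (arm, mism)
        assert hp.arm_len >= 8
        assert hp.left_arm.start <= 50 + 20 + 8  # overlaps the planted stem

    def test_poly_a_tail_has_none(self):
        # homopolymer: any inverted repeat would need A-T complementarity
        element = "C" * 60 + "A" * 50
        assert find_hairpin(element) is None

    def test_longer_arm_preferred(self):
        arm6 = "ACGTAC"
        arm9 = "GACTGACTG"
        region = (
            arm6 + "AA" + reverse_complement(arm6) + "T"
            + arm9 + "AAA" + reverse_complement(arm9) + "T" * 14
        )
        assert len(region) == 50
        hp = find_hairpin("C" * 50 + region)
        assert hp is not None and hp.arm_len >= 9
        # the arm-9 repeat (not the arm-6 one) must be chosen
        assert hp.left_arm.start >= 50 + len(arm6) * 2 + 2

    def test_matches_brute_force_enumeration_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            element = random_dna(rng, 100)
            hp = find_hairpin(element)
            expected = best_inverted_repeat(element[-50:])
            if expected is None:
                assert hp is None
                continue
            arm, mism, right_end, start, loop = expected
            assert hp is not None
            assert hp.arm_len == arm
            assert hp.mismatches == mism
            assert hp.left_arm.start == 50 + start
            assert hp.right_arm.end == 50 + right_end

    def test_element_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            find_hairpin("ACGT")


def _planted_genome(consensus, seed=0, flanks=400):
    """Genome fragment with one hallmark-complete element at a known spot."""
    bp = make_element(consensus, seed=seed)
    rng = np.random.default_rng(seed + 50)
    left = random_dna(rng, flanks - 1) + "A"
    right = "T" + random_dna(rng, flanks - 1)
    genome = NucleotideSequence("frag", left + bp.sequence.residues + right)
    iv = Interval("frag", flanks, flanks + len(bp.sequence))
    return genome, iv, bp


class TestRefineBoundaries:
    def _hit(self, iv, trim5=0, trim3=0):
        return CandidateHit(
            "q",
            Interval(iv.seq_id, iv.start + trim5, iv.end - trim3, iv.strand),
            identity=0.95,
            aln_length=150,
            score=100,
        )

    def test_trimmed_hit_recovers_truth(self, consensus):
        genome, iv, _ = _planted_genome(consensus, seed=1)
        refined = refine_boundaries(self._hit(iv, trim5=7, trim3=7), genome)
        assert (refined.start, refined.end) == (iv.start, iv.end)

    def test_core_only_hit_extends_to_element_end(self, consensus):
        genome, iv, bp = _planted_genome(consensus, seed=2)
        core_hit = CandidateHit(
            "q",
            Interval(iv.seq_id, iv.start, iv.start + len(bp.core_iv)),
            identity=0.95,
            aln_length=134,
            score=100,
        )
        refined = refine_boundaries(core_hit, genome)
        assert (refined.start, refined.end) == (iv.start, iv.end)

    def test_minus_strand_recovered(self, consensus):
        genome, iv, _ = _planted_genome(consensus, seed=3)
        flipped = NucleotideSequence("frag", reverse_complement(genome.residues))
        L = len(genome)
        minus_iv = Interval("frag", L - iv.end + 7, L - iv.start - 7, "-")
        hit = CandidateHit("q", minus_iv, 0.95, 150, 100)
        refined = refine_boundaries(hit, flipped)
        assert (refined.start, refined.end) == (L - iv.end, L - iv.start)
        assert refined.strand == "-"

    def test_no_junction_context_returns_raw_boundaries(self):
        rng = np.random.default_rng(6)
        # G/C-only background cannot contain A|TC or CTRY|T anchors
        genome = NucleotideSequence("r", "".join(rng.choice(list("GC"), size=800)))
        hit = CandidateHit("q", Interval("r", 300, 500), 0.9, 150, 80)
        refined = refine_boundaries(hit, genome)
        assert (refined.start, refined.end) == (300, 500)

    def test_hit_outside_subject_rejected(self):
        genome = NucleotideSequence("r", "ACGT" * 50)
        hit = CandidateHit("q", Interval("r", 100, 300), 0.9, 150, 80)
        with pytest.raises(ValueError):
            refine_boundaries(hit, genome)


class TestDelineateAcquired:
    def test_exact_consensus_plus_tail(self, consensus):
        bp = make_element(consensus, acquired_length=65, seed=4)
        core, acquired, ctrr, ctrr_pos, identity = delineate_acquired(
            bp.sequence.residues, consensus
        )
        assert len(core) == 134
        assert acquired is not None and len(acquired) == 65
        assert ctrr
        assert identity == 1.0

    def test_tail_without_ctrr(self, consensus):
        element = consensus.residues + "G" * 40
        core, acquired, ctrr, _, identity = delineate_acquired(element, consensus)
        assert not ctrr
        assert acquired is not None

    def test_identity_counts_matches_over_ungapped_columns(self, consensus):
        rng = np.random.default_rng(8)
        mutated = list(consensus.residues)
        for pos in rng.choice(np.arange(2, 134), size=14, replace=False):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        _, _, _, _, identity = delineate_acquired("".join(mutated), consensus)
        assert identity == pytest.approx(120 / 134)

    def test_unrelated_sequence_rejected(self, consensus):
        rng = np.random.default_rng(9)
        unrelated = "".join(rng.choice(list("GC"), size=200))
        with pytest.raises(ValueError, match="not a Lep1 candidate"):
            delineate_acquired(unrelated, consensus)


class TestAnnotateElement:
    def test_hallmark_complete_plant_is_full_length(self, consensus):
        genome, iv, bp = _planted_genome(consensus, seed=10)
        (hit,) = find_candidates(consensus, [genome])
        ann = annotate_element(hit, genome, consensus)
        assert ann.full_length
        assert ann.five_prime_tc and ann.three_prime_ctry
        assert ann.ctrr_in_acquired
        assert ann.junction_status == "AT"
        assert ann.tsd_detected is False
        assert ann.hairpin is not None and ann.hairpin.mismatches <= 1
        assert (ann.element_iv.start, ann.element_iv.end) == (iv.start, iv.end)
        assert len(ann.core_iv) + len(ann.acquired_iv) == len(iv)

    def test_destroyed_terminus_region_blocks_full_length(self, consensus):
        genome, iv, bp = _planted_genome(consensus, seed=11)
        residues = list(genome.residues)
        # wipe the whole acquired tail and its hallmarks (CTRY, CTRR,
        # hairpin) so no terminus context survives anywhere nearby
        core_end = iv.start + len(bp.core_iv)
        residues[core_end : iv.end] = ["G"] * (iv.end - core_end)
        broken = NucleotideSequence("frag", "".join(residues))
        (hit,) = find_candidates(consensus, [broken])
        ann = annotate_element(hit, broken, consensus)
        assert not ann.full_length
        assert not ann.three_prime_ctry

    def test_contig_edge_junction_undetermined(self, consensus):
        bp = make_element(consensus, seed=12)
        rng = np.random.default_rng(12)
        genome = NucleotideSequence(
            "edge", bp.sequence.residues + "T" + random_dna(rng, 300)
        )
        hit = CandidateHit("q", Interval("edge", 0, len(bp.sequence)), 0.99, 199, 150)
        with pytest.warns(UserWarning, match="contig edge"):
            ann = annotate_element(hit, genome, consensus)
        assert ann.junction_status == "undetermined"
        assert not ann.full_length
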