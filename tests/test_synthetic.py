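import math

import numpy as np
import pytest

from helitronkit.alignmsa import global_align, identity_excluding_indels
from helitronkit.annotate import detect_termini, find_hairpin
from helitronkit.phylo import p_distance, read_newick
from helitronkit.seqcore import iupac_match, reverse_complement
from helitronkit.synthetic import (
    SimConfig,
    default_consensus,
    jc_evolve,
    make_element,
    mutate,
    plant_insertions,
    random_genome,
    read_config_file,
    simulate_clade,
    simulate_genome,
)


class TestRandomGenome:
    def test_gc_fraction_within_binomial_bound(self):
        g = random_genome(10_000, 0.5, seed=1)
        gc = sum(c in "GC" for c in g.residues) / len(g)
        assert abs(gc - 0.5) < 0.02

    def test_same_seed_reproduces(self):
        assert random_genome(500, 0.4, 7).residues == random_genome(500, 0.4, 7).residues

    def test_gc_one_gives_only_gc(self):
        g = random_genome(300, 1.0, seed=2)
        assert set(g.residues) <= {"G", "C"}

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            random_genome(0, 0.5, 1)
        with pytest.raises(ValueError):
            random_genome(100, 1.5, 1)


class TestMakeElement:
    def test_hallmarks_written_at_recorded_coordinates(self, consensus):
        bp = make_element(consensus, acquired_length=65, seed=3)
        s = bp.sequence.residues
        assert len(s) == 134 + 65
        assert s.startswith("TC")
        assert iupac_match(s[bp.ctry_iv.start : bp.ctry_iv.end], "CTRY")
        assert iupac_match(s[bp.ctrr_iv.start : bp.ctrr_iv.end], "CTRR")
        left = s[bp.hairpin_left.start : bp.hairpin_left.end]
        right = s[bp.hairpin_right.start : bp.hairpin_right.end]
        assert left == reverse_complement(right)
        assert detect_termini(s) == (True, True)

    def test_hairpin_detector_finds_written_hairpin(self, consensus):
        bp = make_element(consensus, seed=4)
        hp = find_hairpin(bp.sequence.residues)
        assert hp is not None
        # the detector's (possibly chance-extended) hairpin overlaps the
        # written one
        assert hp.left_arm.start <= bp.hairpin_left.end
        assert hp.right_arm.end >= bp.hairpin_right.start

    def test_different_seeds_share_core_only(self, consensus):
        a = make_element(consensus, seed=5).sequence.residues
        b = make_element(consensus, seed=6).sequence.residues
        assert a[:134] == b[:134]
        assert a[134:] != b[134:]

    def test_too_small_acquired_rejected(self, consensus):
        with pytest.raises(ValueError):
            make_element(consensus, acquired_length=20)


class TestMutate:
    def test_zero_rates_identity(self, consensus):
        bp = make_element(consensus, seed=1)
        result = mutate(bp.sequence, 0.0, 0.0, seed=1)
        assert result.sequence.residues == bp.sequence.residues
        assert result.n_substitutions == 0

    def test_substitution_bookkeeping_is_exact(self, consensus):
        bp = make_element(consensus, seed=2)
        result = mutate(bp.sequence, 0.05, 0.0, seed=3)
        diffs = sum(
            1 for x, y in zip(bp.sequence.residues, result.sequence.residues)
            if x != y
        )
        assert diffs == result.n_substitutions
        assert len(result.substituted_positions) == result.n_substitutions

    def test_protected_positions_untouched(self, consensus):
        bp = make_element(consensus, seed=4)
        protect = bp.hallmark_positions
        result = mutate(bp.sequence, 0.5, 0.0, seed=5, protect=protect)
        for i in protect:
            assert result.sequence.residues[i] == bp.sequence.residues[i]

    def test_two_percent_divergence_keeps_high_identity(self, consensus):
        bp = make_element(consensus, seed=6)
        high = 0
        trials = 50
        for i in range(trials):
            result = mutate(bp.sequence, 0.02, 0.0, seed=100 + i)
            pair = global_align(bp.sequence.residues, result.sequence.residues)
            if identity_excluding_indels(pair) >= 0.95:
                high += 1
        assert high / trials >= 0.9

    def test_indels_change_length(self, consensus):
        bp = make_element(consensus, seed=7)
        result = mutate(bp.sequence, 0.0, 0.05, seed=8)
        assert result.n_indel_events > 0
        assert len(result.sequence) != len(bp.sequence)


class TestPlantInsertions:
    def test_length_conservation_and_at_junctions(self, consensus):
        genome = random_genome(50_000, 0.4, seed=9)
        bp = make_element(consensus, seed=9)
        genome2, truth = plant_insertions(genome, bp, 5, seed=10)
        assert len(genome2) == len(genome) + 5 * len(bp.sequence)
        assert len(truth) == 5
        for t in truth:
            iv = t.interval
            assert genome2.residues[iv.start : iv.end] == bp.sequence.residues
            assert genome2.residues[iv.start - 1] == "A"
            assert genome2.residues[iv.end] == "T"

    def test_zero_insertions_is_identity(self, consensus):
        genome = random_genome(5_000, 0.4, seed=11)
        bp = make_element(consensus, seed=11)
        genome2, truth = plant_insertions(genome, bp, 0, seed=12)
        assert genome2.residues == genome.residues
        assert truth == []

    def test_insufficient_at_sites_rejected(self, consensus):
        genome = random_genome(2_000, 0.4, seed=13)
        bp = make_element(consensus, seed=13)
        with pytest.raises(ValueError, match="AT sites"):
            plant_insertions(genome, bp, 50, seed=14)

    def test_full_pipeline_recovers_planted_copies(self, consensus):
        """Detection + annotation recovers diverged hallmark-complete plants."""
        from helitronkit.annotate import annotate_element
        from helitronkit.search import find_candidates

        cfg = SimConfig(genome_length=30_000, n_insertions=4, sub_rate=0.10, seed=21)
        genome, truth, cons, _ = simulate_genome(cfg)
        hits = find_candidates(cons, [genome])
        assert len(hits) == 4
        for hit, t in zip(hits, truth):
            ann = annotate_element(hit, genome, cons)
            assert ann.full_length
            assert abs(ann.element_iv.start - t.interval.start) <= 2
            assert abs(ann.element_iv.end - t.interval.end) <= 2


class TestSimulateClade:
    HOST = "((A:0.05,B:0.05):0.02,(C:0.05,D:0.05):0.02);"

    def test_vertical_descent_tracks_host_paths(self, consensus):
        host = read_newick(self.HOST)
        element = make_element(consensus, seed=15).sequence
        _, elements, _ = simulate_clade(host, element, seed=16)
        names, mat = host.leaf_distance_matrix()
        idx = {n: i for i, n in enumerate(names)}
        for a, b in (("A", "B"), ("A", "C"), ("B", "D")):
            pair = global_align(elements[a].residues, elements[b].residues)
            p = p_distance(pair)
            path = mat[idx[a], idx[b]]
            expected_p = 0.75 * (1 - math.exp(-4 * path / 3))
            se = math.sqrt(expected_p * (1 - expected_p) / len(element))
            assert abs(p - expected_p) <= 3 * se + 1e-9

    def test_ht_event_makes_recipient_resemble_donor(self, consensus):
        host = read_newick(self.HOST)
        element = make_element(consensus, seed=17).sequence
        _, vertical, _ = simulate_clade(host, element, seed=18)
        _, with_ht, _ = simulate_clade(host, element, ht_events=[("A", "D")], seed=18)
        pv = p_distance(global_align(vertical["A"].residues, vertical["D"].residues))
        ph = p_distance(global_align(with_ht["A"].residues, with_ht["D"].residues))
        assert ph < pv

    def test_same_seed_reproduces(self, consensus):
        host = read_newick(self.HOST)
        element = make_element(consensus, seed=19).sequence
        g1, e1, t1 = simulate_clade(host, element, seed=20)
        g2, e2, t2 = simulate_clade(host, element, seed=20)
        assert {k: v.residues for k, v in g1.items()} == {
            k: v.residues for k, v in g2.items()
        }
        assert {k: v.residues for k, v in e1.items()} == {
            k: v.residues for k, v in e2.items()
        }

    def test_genomes_contain_the_final_elements(self, consensus):
        host = read_newick(self.HOST)
        element = make_element(consensus, seed=21).sequence
        genomes, elements, truth = simulate_clade(host, element, seed=22)
        by_taxon = {t.interval.seq_id: t for t in truth}
        for taxon, genome in genomes.items():
            t = by_taxon[f"{taxon}_genome"]
            iv = t.interval
            assert genome.residues[iv.start : iv.end] == elements[taxon].residues

    def test_unknown_taxon_in_ht_event_rejected(self, consensus):
        host = read_newick(self.HOST)
        element = make_element(consensus, seed=23).sequence
        with pytest.raises(ValueError):
            simulate_clade(host, element, ht_events=[("A", "Z")], seed=24)


class TestSimConfigIo:
    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(genome_length=1000, n_insertions=10)

    def test_config_file_roundtrip(self, tmp_path):
        p = tmp_path / "sim.cfg"
        p.write_text(
            "genome_length = 20000\nn_insertions = 3\nsub_rate = 0.05\nseed = 42\n"
        )
        cfg = read_config_file(p)
        assert (cfg.genome_length, cfg.n_insertions, cfg.sub_rate, cfg.seed) == (
            20000, 3, 0.05, 42,
        )

    def test_unknown_key_lists_valid_keys(self, tmp_path):
        p = tmp_path / "sim.cfg"
        p.write_text("genom_length = 20000\n")
        with pytest.raises(ValueError, match="genome_length"):
            read_config_file(p)


class TestJcEvolve:
    def test_zero_branch_is_identity(self, consensus):
        rng = np.random.default_rng(0)
        out = jc_evolve(consensus, 0.0, rng)
        assert out.residues == consensus.residues

    def test_mean_identity_matches_sub_rate(self, consensus):
        """Mean identity of copies mutated at rate s is within 0.02 of 1-s."""
        bp = make_element(consensus, seed=30)
        identities = []
        for i in range(50):
            result = mutate(bp.sequence, 0.05, 0.0, seed=500 + i)
            diffs = sum(
                1 for x, y in zip(bp.sequence.residues, result.sequence.residues)
                if x != y
            )
            identities.append(1 - diffs / len(bp.sequence))
        assert abs(np.mean(identities) - 0.95) <= 0.02
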