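"""End-to-end evaluation experiments on synthetic data.

Each function sets up a defined study condition — hallmark-complete
planted elements at a stated divergence, noise-free occupancy triples,
a clade with one horizontal transfer between its two most distant taxa,
a perfectly congruent alignment — runs the pipeline on it, and returns
summary statistics.  The experiments are sized for a desk-scale run
(single CPU, seconds to a couple of minutes each).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignmsa import MultipleAlignment
from .annotate import annotate_element
from .phylo import (
    DistanceMatrix,
    bootstrap,
    neighbor_joining,
    read_newick,
    robinson_foulds,
    to_newick,
)
from .polymorphism import build_chimeric_query, classify_site, ht_scan
from .search import find_candidates
from .seqcore import Interval, NucleotideSequence
from .synthetic import (
    SimConfig,
    default_consensus,
    make_element,
    random_genome,
    simulate_clade,
    simulate_genome,
)


def planted_recovery(
    n_genomes: int = 10,
    n_per_genome: int = 10,
    sub_rate: float = 0.10,
    genome_length: int = 60_000,
    seed: int = 0,
) -> dict:
    """Detection sensitivity and boundary accuracy on planted elements.

    ``n_genomes * n_per_genome`` hallmark-complete copies at
    ``sub_rate`` substitution divergence are planted into independent
    random genomes; the standard scan (70% identity over >100 columns,
    hallmark-anchored boundary refinement) is run on each.  Returns the
    fraction of plants detected and, among detected copies, the
    fraction whose refined boundaries are within +/-2 bp of truth at
    both ends.
    """
    detected = 0
    boundary_ok = 0
    total = 0
    for g in range(n_genomes):
        cfg = SimConfig(
            genome_length=genome_length,
            n_insertions=n_per_genome,
            sub_rate=sub_rate,
            seed=seed + g,
        )
        genome, truth, consensus, _ = simulate_genome(cfg)
        hits = find_candidates(consensus, [genome])
        annotations = [annotate_element(h, genome, consensus) for h in hits]
        total += len(truth)
        for t in truth:
            overlapping = [
                a for a in annotations
                if a.element_iv.start < t.interval.end
                and t.interval.start < a.element_iv.end
            ]
            if not overlapping:
                continue
            detected += 1
            a = overlapping[0]
            if (
                abs(a.element_iv.start - t.interval.start) <= 2
                and abs(a.element_iv.end - t.interval.end) <= 2
            ):
                boundary_ok += 1
    return {
        "n_planted": total,
        "sensitivity": detected / total,
        "boundary_within_2bp": boundary_ok / detected if detected else 0.0,
    }


def emptysite_accuracy(n_triples: int = 10, seed: int = 0) -> dict:
    """Occupancy classification on noise-free synthetic site triples.

    For each of ``n_triples`` loci an occupied donor locus is built;
    the chimeric flank query is then classified against the empty
    orthologue, the occupied locus itself, and an unrelated sequence
    (3 targets per locus).  Returns overall accuracy and the largest
    insert-length estimation error on the occupied targets.
    """
    rng = np.random.default_rng(seed)
    consensus = default_consensus()
    correct = 0
    max_insert_error = 0
    total = 0
    for i in range(n_triples):
        locus = random_genome(600, 0.4, int(rng.integers(2**31))).residues
        element = make_element(
            consensus, seed=int(rng.integers(2**31))
        ).sequence.residues
        occupied = locus[:300] + element + locus[300:]
        donor = NucleotideSequence("donor", occupied)
        query, junction = build_chimeric_query(
            donor, Interval("donor", 300, 300 + len(element))
        )
        targets = {
            "empty": NucleotideSequence("empty", locus),
            "occupied": donor,
            "absent": NucleotideSequence(
                "absent", random_genome(600, 0.4, int(rng.integers(2**31))).residues
            ),
        }
        for expected, target in targets.items():
            call = classify_site(query, target, junction)
            total += 1
            if call.status == expected:
                correct += 1
            if expected == "occupied" and call.insert_length_estimate is not None:
                max_insert_error = max(
                    max_insert_error, abs(call.insert_length_estimate - len(element))
                )
    return {
        "n_sites": total,
        "accuracy": correct / total,
        "max_insert_error_bp": max_insert_error,
    }


#: 6-taxon host tree used by the HT experiment; A and F are the unique
#: most distant pair (path 0.5 substitutions/site)
HT_HOST_TREE = (
    "(((A:0.2,B:0.15):0.05,(C:0.15,D:0.15):0.05):0.025,(E:0.15,F:0.2):0.025);"
)


def ht_flag_experiment(
    n_reps: int = 20, seed: int = 0, acquired_length: int = 311
) -> dict:
    """Horizontal-transfer flagging end to end.

    In each replicate an element evolves down the 6-taxon host tree with
    one HT event from A to F (its most distant taxon); every taxon pair
    is then screened with the vertical-expectation test (margin 0.10,
    rate matched to the simulation's substitutions/site units).  A
    replicate counts as correct when (A, F) — and no other pair — is
    flagged.  Divergences stay below 0.5 subs/site, where the
    alignment-based identity tracks the analytic expectation; the
    445-bp element keeps binomial noise on identity small.
    """
    host = read_newick(HT_HOST_TREE)
    consensus = default_consensus()
    correct = 0
    false_flags = 0
    missed = 0
    for rep in range(n_reps):
        element = make_element(
            consensus, acquired_length=acquired_length, seed=seed + rep
        ).sequence
        _, elements, _ = simulate_clade(
            host, element, ht_events=[("A", "F")], seed=seed + 1000 + rep
        )
        records = ht_scan(elements, host)
        flagged = {r.taxon_pair for r in records if r.flagged}
        if flagged == {("A", "F")}:
            correct += 1
        if ("A", "F") not in flagged:
            missed += 1
        false_flags += len(flagged - {("A", "F")})
    return {
        "n_reps": n_reps,
        "exactly_correct_fraction": correct / n_reps,
        "missed_transfers": missed,
        "false_flags": false_flags,
    }


def congruent_alignment(n_taxa: int = 10, n_columns: int = 200) -> tuple[MultipleAlignment, str]:
    """Homoplasy-free alignment on a fixed 10-taxon tree.

    Every column marks exactly one branch, so p-distances are exactly
    additive on the generating topology for any column resample and
    neighbor joining recovers it in every bootstrap replicate.
    """
    if n_taxa != 10:
        raise ValueError("the fixed design covers 10 taxa")
    newick = "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1,(I:1,J:1):1);"
    taxa = list("ABCDEFGHIJ")
    internal = [
        set("AB"), set("CD"), set("EF"), set("GH"), set("IJ"),
        set("ABCD"), set("EFGH"),
    ]
    terminal = [{t} for t in taxa]
    columns: list[set] = []
    per_internal = max(10, (n_columns // 2) // len(internal))
    for clade in internal:
        columns.extend([clade] * per_internal)
    remaining = n_columns - len(columns)
    i = 0
    while len(columns) < n_columns:
        columns.append(terminal[i % len(terminal)])
        i += 1
    rows = [
        "".join("G" if taxon in col else "A" for col in columns)
        for taxon in taxa
    ]
    return MultipleAlignment(tuple(taxa), tuple(rows)), newick


def bootstrap_congruent(n_reps: int = 1000, seed: int = 0) -> dict:
    """Bootstrap a perfectly congruent 10x200 alignment.

    Returns the minimum internal-edge support (should be 100), whether
    the point tree matches the generating topology, and whether a rerun
    with the same seed is byte-identical.
    """
    msa, newick = congruent_alignment()
    tree = bootstrap(msa, n_reps=n_reps, seed=seed)
    rerun = bootstrap(msa, n_reps=n_reps, seed=seed)
    supports = [n.support for n in tree.internal_edges()]
    return {
        "n_reps": n_reps,
        "n_internal_edges": len(supports),
        "min_support": min(supports),
        "topology_recovered": robinson_foulds(tree, read_newick(newick)) == 0,
        "seed_reproducible": to_newick(tree, 0) == to_newick(rerun, 0),
    }


def random_additive_tree(rng: np.random.Generator, n_leaves: int) -> str:
    """Random binary topology, branch lengths uniform on [0.05, 1]."""
    nodes = [f"T{i}:{rng.uniform(0.05, 1.0):.6f}" for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.05, 1.0):.6f}"
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


def nj_additive_recovery(n_trees: int = 50, seed: int = 0) -> dict:
    """Exact topology recovery of random additive trees (4-8 taxa)."""
    rng = np.random.default_rng(seed)
    recovered = 0
    for _ in range(n_trees):
        n = int(rng.integers(4, 9))
        newick = random_additive_tree(rng, n)
        generating = read_newick(newick)
        labels, mat = generating.leaf_distance_matrix()
        order = np.argsort(labels)
        D = DistanceMatrix(
            tuple(labels[i] for i in order), mat[np.ix_(order, order)]
        )
        tree = neighbor_joining(D)
        if robinson_foulds(tree, generating) == 0:
            recovered += 1
    return {"n_trees": n_trees, "recovery_rate": recovered / n_trees}
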