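"""Synthetic host genomes with planted, hallmark-complete elements.

The generator emulates the data regime the pipeline is built for:
random host background at insect-like GC content, planted copies of a
short non-autonomous Helitron (conserved core + species-specific
acquired 3' tail), each copy carrying the family hallmarks — 5'-TC
start, 3'-CTRY terminus, a CTRR tetramer in the last bases of the
acquired tail, a perfect 8-bp-arm/4-bp-loop hairpin ending upstream of
the terminus — inserted precisely between a host ``A`` and ``T``
without target-site duplication.  Every construction returns exact
truth coordinates so recovery can be scored.

Defaults mirror the biological regime: a 134-bp conserved core, a
65-bp acquired tail (about 199 bp per element) and within-family
divergence of a few percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .phylo import PhyloTree, TreeNode
from .seqcore import Interval, NucleotideSequence, reverse_complement

BASES = np.array(list("ACGT"))

CORE_LENGTH = 134          # conserved-core length of the family
DEFAULT_ACQUIRED = 65      # acquired-tail length
DEFAULT_GC = 0.40          # insect-genome-like GC content
HAIRPIN_ARM = 8
HAIRPIN_LOOP = 4
HAIRPIN_END_OFFSET = 10    # hairpin right arm ends this far before the terminus
MIN_ACQUIRED = 30          # room for hairpin + CTRR + CTRY without overlap


@dataclass(frozen=True)
class ElementBlueprint:
    """Construction record of a synthetic element (element coordinates)."""

    sequence: NucleotideSequence
    core_iv: Interval
    acquired_iv: Interval
    hairpin_left: Interval
    hairpin_right: Interval
    ctrr_iv: Interval
    ctry_iv: Interval

    @property
    def hallmark_positions(self) -> set[int]:
        """Positions that must stay intact for the copy to remain
        hallmark-complete."""
        positions = {0, 1}
        for iv in (self.hairpin_left, self.hairpin_right, self.ctrr_iv, self.ctry_iv):
            positions.update(range(iv.start, iv.end))
        return positions


@dataclass(frozen=True)
class TruthRecord:
    element_id: str
    interval: Interval            # genome coordinates, final coordinate system
    divergence_applied: float     # realized substitutions / element length
    junction: tuple[str, str]     # host base before and after the insertion
    hairpin_left: Interval        # element coordinates
    hairpin_right: Interval
    acquired_iv: Interval


@dataclass(frozen=True)
class MutationResult:
    sequence: NucleotideSequence
    n_substitutions: int
    n_indel_events: int
    substituted_positions: tuple[int, ...]


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 60_000
    gc_fraction: float = DEFAULT_GC
    n_insertions: int = 10
    consensus: Optional[NucleotideSequence] = None
    acquired_length: int = DEFAULT_ACQUIRED
    sub_rate: float = 0.02
    indel_rate: float = 0.0
    flank_min: int = 150
    seed: int = 0
    protect_hallmarks: bool = True

    def __post_init__(self) -> None:
        for name in ("sub_rate", "indel_rate", "gc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        element_len = (
            len(self.consensus) if self.consensus is not None else CORE_LENGTH
        ) + self.acquired_length
        if self.genome_length < self.n_insertions * (element_len + 2 * self.flank_min):
            raise ValueError(
                "genome_length too small for n_insertions with the required flanks"
            )


def random_genome(length: int, gc_fraction: float, seed: int) -> NucleotideSequence:
    """I.i.d. background sequence with the requested GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [
        (1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2,
    ]
    residues = "".join(rng.choice(BASES, size=length, p=probs))
    return NucleotideSequence(f"synthgenome_seed{seed}", residues)


def default_consensus(seed: int = 2014) -> NucleotideSequence:
    """A fixed synthetic 134-bp family consensus beginning ``TC``.

    This is a stand-in reference sequence generated by this module, not
    a published consensus; it plays the role of the conserved core in
    all simulations.
    """
    rng = np.random.default_rng(seed)
    body = "".join(rng.choice(BASES, size=CORE_LENGTH - 2))
    return NucleotideSequence(
        "synthetic_core_consensus", "TC" + body,
        "synthetic 134 bp conserved-core consensus",
    )


def make_element(
    consensus: NucleotideSequence,
    acquired_length: int = DEFAULT_ACQUIRED,
    seed: int = 0,
    element_id: str = "synthetic_element",
) -> ElementBlueprint:
    """Consensus core plus a random acquired tail carrying all hallmarks.

    The tail receives a perfect 8-bp-arm / 4-bp-loop hairpin ending
    ``HAIRPIN_END_OFFSET`` bases before the terminus, a ``CTRR``
    tetramer within the last 15 bases, and a terminal ``CTRY``.
    """
    if acquired_length < MIN_ACQUIRED:
        raise ValueError(
            f"acquired_length must be >= {MIN_ACQUIRED} to fit hairpin + motifs"
        )
    rng = np.random.default_rng(seed)
    core = consensus.residues
    if not core.startswith("TC"):
        core = "TC" + core[2:]
    tail = list(rng.choice(BASES, size=acquired_length))
    L = acquired_length
    # terminal CTRY
    ctry = "CT" + rng.choice(["A", "G"]) + rng.choice(["C", "T"])
    tail[L - 4 : L] = list(ctry)
    # CTRR immediately before it (within the last 15 bases of the tail)
    ctrr = "CT" + rng.choice(["A", "G"]) + rng.choice(["A", "G"])
    tail[L - 8 : L - 4] = list(ctrr)
    # perfect hairpin ending HAIRPIN_END_OFFSET before the terminus
    arm, loop = HAIRPIN_ARM, HAIRPIN_LOOP
    h_right_end = L - HAIRPIN_END_OFFSET
    h_left_start = h_right_end - (2 * arm + loop)
    left_arm = "".join(rng.choice(BASES, size=arm))
    tail[h_left_start : h_left_start + arm] = list(left_arm)
    tail[h_right_end - arm : h_right_end] = list(reverse_complement(left_arm))

    core_len = len(core)
    residues = core + "".join(tail)
    seq = NucleotideSequence(element_id, residues)
    return ElementBlueprint(
        sequence=seq,
        core_iv=Interval(element_id, 0, core_len),
        acquired_iv=Interval(element_id, core_len, core_len + L),
        hairpin_left=Interval(
            element_id, core_len + h_left_start, core_len + h_left_start + arm
        ),
        hairpin_right=Interval(
            element_id, core_len + h_right_end - arm, core_len + h_right_end
        ),
        ctrr_iv=Interval(element_id, core_len + L - 8, core_len + L - 4),
        ctry_iv=Interval(element_id, core_len + L - 4, core_len + L),
    )


def mutate(
    seq: NucleotideSequence,
    sub_rate: float,
    indel_rate: float,
    seed: int,
    protect: Optional[set[int]] = None,
) -> MutationResult:
    """Apply per-site substitutions and short indels.

    Each site substitutes with probability ``sub_rate`` (uniform over
    the three alternatives) and initiates an indel with probability
    ``indel_rate`` (insertion or deletion equally likely, length
    geometric with mean 2).  Positions in ``protect`` are exempt.
    """
    for name, v in (("sub_rate", sub_rate), ("indel_rate", indel_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    protect = protect or set()
    s = seq.residues
    out: list[str] = []
    n_subs = 0
    n_indels = 0
    sub_positions: list[int] = []
    i = 0
    while i < len(s):
        base = s[i]
        if i in protect:
            out.append(base)
            i += 1
            continue
        if indel_rate > 0 and rng.random() < indel_rate:
            n_indels += 1
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                out.append("".join(rng.choice(BASES, size=length)))
                out.append(base)
                i += 1
            else:
                # delete up to `length` bases starting here, keeping any
                # protected positions intact
                deleted = 0
                while i < len(s) and deleted < length:
                    if i in protect:
                        out.append(s[i])
                    else:
                        deleted += 1
                    i += 1
            continue
        if sub_rate > 0 and rng.random() < sub_rate:
            alternatives = [b for b in "ACGT" if b != base]
            out.append(rng.choice(alternatives))
            n_subs += 1
            sub_positions.append(i)
        else:
            out.append(base)
        i += 1
    residues = "".join(out)
    return MutationResult(
        NucleotideSequence(seq.id, residues, seq.description),
        n_subs,
        n_indels,
        tuple(sub_positions),
    )


def plant_insertions(
    genome: NucleotideSequence,
    element: NucleotideSequence | ElementBlueprint,
    n: int,
    flank_min: int = 150,
    seed: int = 0,
    variants: Optional[Sequence[NucleotideSequence]] = None,
    blueprint: Optional[ElementBlueprint] = None,
) -> tuple[NucleotideSequence, list[TruthRecord]]:
    """Insert ``n`` element copies between host A/T dinucleotides.

    Each copy goes precisely between the ``A`` and ``T`` of a chosen
    ``AT`` dinucleotide (so the host reads ...A | element | T...), with
    no target-site duplication, pairwise separation and contig-edge
    clearance of at least ``flank_min``.  ``variants`` may supply
    per-copy (e.g. mutated) sequences; otherwise the same element is
    used for every copy.  Truth intervals are reported in the final
    coordinate system.
    """
    if isinstance(element, ElementBlueprint):
        blueprint = blueprint or element
        element = element.sequence
    if n == 0:
        return genome, []
    copies = list(variants) if variants is not None else [element] * n
    if len(copies) != n:
        raise ValueError("variants must provide one sequence per insertion")

    s = genome.residues
    rng = np.random.default_rng(seed)
    at_sites = [
        i for i in range(flank_min, len(s) - flank_min - 1)
        if s[i] == "A" and s[i + 1] == "T"
    ]
    rng.shuffle(at_sites)
    chosen: list[int] = []
    max_len = max(len(c) for c in copies)
    min_sep = 2 * flank_min + max_len
    for site in at_sites:
        if all(abs(site - c) >= min_sep for c in chosen):
            chosen.append(site)
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise ValueError(
            f"genome has only {len(chosen)} usable AT sites with "
            f"flank_min={flank_min}; requested {n}"
        )
    chosen.sort()

    pieces: list[str] = []
    truth: list[TruthRecord] = []
    prev = 0
    offset = 0
    for idx, site in enumerate(chosen):
        copy = copies[idx]
        pieces.append(s[prev : site + 1])
        start = site + 1 + offset
        iv = Interval(genome.id, start, start + len(copy))
        divergence = (
            _hamming(element.residues, copy.residues) / len(element)
            if len(copy) == len(element)
            else float("nan")
        )
        hp_l = blueprint.hairpin_left if blueprint else Interval(copy.id, 0, 1)
        hp_r = blueprint.hairpin_right if blueprint else Interval(copy.id, 1, 2)
        acq = blueprint.acquired_iv if blueprint else Interval(copy.id, 0, len(copy))
        truth.append(
            TruthRecord(
                element_id=f"{copy.id}_{idx + 1}",
                interval=iv,
                divergence_applied=divergence,
                junction=("A", "T"),
                hairpin_left=hp_l,
                hairpin_right=hp_r,
                acquired_iv=acq,
            )
        )
        pieces.append(copy.residues)
        offset += len(copy)
        prev = site + 1
    pieces.append(s[prev:])
    new_genome = NucleotideSequence(genome.id, "".join(pieces), genome.description)
    return new_genome, truth


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def simulate_genome(
    config: SimConfig,
) -> tuple[NucleotideSequence, list[TruthRecord], NucleotideSequence, ElementBlueprint]:
    """End-to-end simulation: background genome + n diverged planted copies.

    Returns (genome, truth, consensus, blueprint).  Per-copy divergence
    is applied before planting; with ``protect_hallmarks`` the hallmark
    positions are exempt from mutation so every copy stays
    hallmark-complete.
    """
    consensus = config.consensus or default_consensus()
    genome = random_genome(config.genome_length, config.gc_fraction, config.seed)
    bp = make_element(consensus, config.acquired_length, seed=config.seed + 1)
    protect = bp.hallmark_positions if config.protect_hallmarks else None
    variants = [
        mutate(
            bp.sequence, config.sub_rate, config.indel_rate,
            seed=config.seed + 100 + i, protect=protect,
        ).sequence
        for i in range(config.n_insertions)
    ]
    genome2, truth = plant_insertions(
        genome, bp.sequence, config.n_insertions,
        flank_min=config.flank_min, seed=config.seed + 2,
        variants=variants, blueprint=bp,
    )
    return genome2, truth, consensus, bp


# ---------------------------------------------------------------------------
# clade simulation (vertical descent + optional horizontal transfer)
# ---------------------------------------------------------------------------

def jc_evolve(seq: NucleotideSequence, branch_length: float, rng) -> NucleotideSequence:
    """Evolve a sequence along a branch under Jukes-Cantor.

    ``branch_length`` is in expected substitutions/site; each site
    changes with probability ``(3/4)(1 - exp(-4b/3))``, uniformly over
    the three alternative bases (the exact JC transition kernel, so
    multiple hits are accounted for)."""
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    p_change = 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))
    residues = np.array(list(seq.residues))
    hit = rng.random(len(residues)) < p_change
    if hit.any():
        for i in np.nonzero(hit)[0]:
            alternatives = [b for b in "ACGT" if b != residues[i]]
            residues[i] = alternatives[rng.integers(3)]
    return NucleotideSequence(seq.id, "".join(residues), seq.description)


def simulate_clade(
    host_tree: PhyloTree,
    element: NucleotideSequence,
    ht_events: Sequence[tuple[str, str]] = (),
    seed: int = 0,
    genome_length: int = 3000,
    gc_fraction: float = DEFAULT_GC,
) -> tuple[dict[str, NucleotideSequence], dict[str, NucleotideSequence], list[TruthRecord]]:
    """Evolve an element down a host tree, with optional horizontal
    transfer events, and plant each taxon's final copy in its genome.

    Branch lengths are in substitutions/site.  Each ``(donor,
    recipient)`` event (leaf names) replaces the recipient's inherited
    element with the donor's tip-state element at the start of the
    recipient's terminal branch; the transferred copy then evolves
    along that branch.  Returns (per-taxon genomes, per-taxon element
    sequences, truth records).
    """
    rng = np.random.default_rng(seed)
    leaf_names = host_tree.leaf_names
    for donor, recipient in ht_events:
        if donor not in leaf_names or recipient not in leaf_names:
            raise ValueError(f"unknown taxon in HT event ({donor}, {recipient})")
        if donor == recipient:
            raise ValueError("HT donor and recipient must differ")

    tip_states: dict[str, NucleotideSequence] = {}
    branch_lengths: dict[str, float] = {}

    def descend(node: TreeNode, state: NucleotideSequence) -> None:
        evolved = jc_evolve(state, node.length, rng)
        if node.is_leaf():
            tip_states[node.name] = evolved
            branch_lengths[node.name] = node.length
            return
        for child in node.children:
            descend(child, evolved)

    root_state = NucleotideSequence(element.id, element.residues)
    for child in host_tree.root.children:
        descend(child, root_state)

    # HT: recipient restarts its terminal branch from the donor's tip state
    for donor, recipient in ht_events:
        transferred = NucleotideSequence(
            element.id, tip_states[donor].residues,
            f"horizontal transfer {donor}->{recipient}",
        )
        tip_states[recipient] = jc_evolve(
            transferred, branch_lengths[recipient], rng
        )

    genomes: dict[str, NucleotideSequence] = {}
    truth: list[TruthRecord] = []
    for i, taxon in enumerate(leaf_names):
        background = random_genome(
            genome_length, gc_fraction, int(rng.integers(2**31))
        )
        background = NucleotideSequence(
            f"{taxon}_genome", background.residues
        )
        copy = NucleotideSequence(f"{taxon}_element", tip_states[taxon].residues)
        genome, records = plant_insertions(
            background, copy, 1, flank_min=min(150, genome_length // 4),
            seed=int(rng.integers(2**31)),
        )
        genomes[taxon] = genome
        truth.extend(records)
        tip_states[taxon] = copy
    return genomes, tip_states, truth


# ---------------------------------------------------------------------------
# truth / config i/o
# ---------------------------------------------------------------------------

def write_truth_tsv(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "element_id\tseq_id\tstart\tend\tstrand\tdivergence\t"
            "junction\thairpin_left\thairpin_right\tacquired\n"
        )
        for t in truth:
            iv = t.interval
            fh.write(
                f"{t.element_id}\t{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{t.divergence_applied:.4f}\t{t.junction[0]}|{t.junction[1]}\t"
                f"{t.hairpin_left.start}-{t.hairpin_left.end}\t"
                f"{t.hairpin_right.start}-{t.hairpin_right.end}\t"
                f"{t.acquired_iv.start}-{t.acquired_iv.end}\n"
            )


def write_truth_gff3(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in truth:
            iv = t.interval
            fh.write(
                f"{iv.seq_id}\thelitronkit_sim\tmobile_genetic_element\t"
                f"{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f"ID={t.element_id};divergence={t.divergence_applied:.4f}\n"
            )


def read_config_file(path: str | Path) -> SimConfig:
    """Parse a plain key=value config file into a :class:`SimConfig`."""
    valid = {f.name for f in SimConfig.__dataclass_fields__.values()}
    kwargs: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, value = (x.strip() for x in line.split("=", 1))
            if key not in valid or key == "consensus":
                raise ValueError(
                    f"{path}:{lineno}: unknown key {key!r}; valid keys: "
                    + ", ".join(sorted(valid - {"consensus"}))
                )
            f_type = SimConfig.__dataclass_fields__[key].type
            if "int" in str(f_type):
                kwargs[key] = int(value)
            elif "float" in str(f_type):
                kwargs[key] = float(value)
            elif "bool" in str(f_type):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = value
    return SimConfig(**kwargs)
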