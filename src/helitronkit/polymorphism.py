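"""Insertion-polymorphism assessment and horizontal-transfer evidence.

Empty-site analysis follows the chimeric-query approach: the ~100 bp
flanks on either side of an insertion are joined into a ~200 bp query;
a target locus where the two halves align contiguously is an *empty*
orthologous/paralogous site, a target where the halves are split by an
intervening stretch is *occupied*, anything else is *absent*.

Horizontal-transfer evidence formalises the classic argument: an
element shared by two hosts is flagged when its observed identity
exceeds, by a configurable margin, the identity expected under neutral
vertical descent since the hosts diverged (Jukes-Cantor expectation
with two lineages of length ``rate * T``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignmsa import global_align, identity_excluding_indels
from .phylo import PhyloTree, TreeNode
from .search import local_align
from .seqcore import Interval, NucleotideSequence, reverse_complement

#: default neutral substitution rate, substitutions / site / year / lineage
DEFAULT_RATE = 2e-9


@dataclass(frozen=True)
class OccupancyCall:
    site_id: str
    status: str  # "occupied" | "empty" | "absent"
    evidence: tuple[Interval, ...]
    insert_length_estimate: Optional[int]


@dataclass(frozen=True)
class HTEvidence:
    taxon_pair: tuple[str, str]
    observed_identity: float
    divergence_time: float
    assumed_rate: float
    expected_identity: float
    margin: float
    flagged: bool


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Boolean presence of each element family in each taxon."""

    taxa: tuple[str, ...]
    elements: tuple[str, ...]
    presence: np.ndarray  # bool, taxa x elements

    def __post_init__(self) -> None:
        if self.presence.shape != (len(self.taxa), len(self.elements)):
            raise ValueError("presence shape does not match taxa/elements")

    def present_taxa(self, element: str) -> list[str]:
        j = self.elements.index(element)
        return [t for i, t in enumerate(self.taxa) if self.presence[i, j]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence, index=list(self.taxa), columns=list(self.elements)
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().astype(int).to_csv(path, index_label="taxon")


def build_chimeric_query(
    genome: NucleotideSequence, element_iv: Interval, flank: int = 100
) -> tuple[NucleotideSequence, int]:
    """Join the two ~``flank``-bp host flanks across an insertion.

    Returns the query and the junction offset within it (the number of
    upstream bases, normally ``flank``).  Flanks are taken in element
    orientation and truncated at contig ends with a warning.
    """
    if element_iv.end > len(genome):
        raise ValueError(
            f"element interval [{element_iv.start}, {element_iv.end}) outside "
            f"{genome.id!r} (length {len(genome)})"
        )
    s = genome.residues
    left = s[max(0, element_iv.start - flank) : element_iv.start]
    right = s[element_iv.end : element_iv.end + flank]
    if len(left) < flank or len(right) < flank:
        warnings.warn(
            f"flank truncated at contig edge of {genome.id!r}: "
            f"upstream {len(left)} bp, downstream {len(right)} bp",
            stacklevel=2,
        )
    if element_iv.strand == "-":
        upstream, downstream = reverse_complement(right), reverse_complement(left)
    else:
        upstream, downstream = left, right
    junction = element_iv.start if element_iv.strand == "+" else element_iv.end
    query = NucleotideSequence(
        f"{genome.id}:emptysite:{junction}",
        upstream + downstream,
        f"chimeric empty-site query, junction at offset {len(upstream)}",
    )
    return query, len(upstream)


def classify_site(
    query: NucleotideSequence,
    target: NucleotideSequence,
    junction: Optional[int] = None,
    min_identity: float = 0.70,
    min_flank_hit: int = 50,
    min_insert: int = 50,
    junction_slop: int = 10,
) -> OccupancyCall:
    """Classify a target locus as empty, occupied or absent.

    The two halves of the chimeric query are aligned to the target
    independently (better strand kept).  *empty*: both halves hit
    collinearly with at least ``min_flank_hit`` aligned bases each and
    essentially no intervening target sequence (within
    ``junction_slop``).  *occupied*: both halves hit with an
    intervening stretch of at least ``min_insert`` bases, reported as
    the insert length estimate.  Anything else is *absent*.
    """
    if junction is None:
        junction = len(query) // 2
    up_half = query.residues[:junction]
    down_half = query.residues[junction:]

    best = None
    for strand, t in (("+", target.residues), ("-", reverse_complement(target.residues))):
        up = _half_hit(up_half, t, min_identity, min_flank_hit)
        down = _half_hit(down_half, t, min_identity, min_flank_hit)
        score = (up[2] if up else 0.0) + (down[2] if down else 0.0)
        if best is None or score > best[0]:
            best = (score, strand, t, up, down)
    _, strand, t, up, down = best

    evidence: list[Interval] = []
    tlen = len(target)

    def to_interval(t_start: int, t_end: int) -> Interval:
        if strand == "+":
            return Interval(target.id, t_start, t_end, "+")
        return Interval(target.id, tlen - t_end, tlen - t_start, "-")

    if up is None or down is None:
        return OccupancyCall(query.id, "absent", tuple(), None)

    (u_qs, u_qe, _, u_ts, u_te) = up[3]
    (d_qs, d_qe, _, d_ts, d_te) = down[3]
    evidence = [to_interval(u_ts, u_te), to_interval(d_ts, d_te)]
    # target separation corrected for unaligned query ends around the junction
    unaligned = (len(up_half) - u_qe) + d_qs
    gap = (d_ts - u_te) - unaligned
    if abs(gap) <= junction_slop:
        return OccupancyCall(query.id, "empty", tuple(evidence), None)
    if gap >= min_insert:
        return OccupancyCall(query.id, "occupied", tuple(evidence), int(gap))
    return OccupancyCall(query.id, "absent", tuple(evidence), None)


def _half_hit(half: str, target: str, min_identity: float, min_cols: int):
    """Best local hit of one query half; None if below thresholds."""
    try:
        aln = local_align(half, target)
    except ValueError:
        return None
    if aln.n_ungapped_columns == 0:
        return None
    if aln.n_ungapped_columns < min_cols or aln.identity < min_identity:
        return None
    coords = (aln.a_start, aln.a_end, aln.identity, aln.b_start, aln.b_end)
    return (aln.identity, aln.n_ungapped_columns, aln.score, coords)


def expected_vertical_identity(T: float, rate: float) -> float:
    """Jukes-Cantor expected identity after ``T`` years of independent
    evolution in two lineages at ``rate`` substitutions/site/year each.

    ``1 - p`` with ``p = (3/4)(1 - exp(-8 rate T / 3))`` (total expected
    substitutions per site across both lineages is ``2 rate T``).
    """
    if T < 0 or rate <= 0:
        raise ValueError("T must be >= 0 and rate > 0")
    p = 0.75 * (1.0 - math.exp(-8.0 * rate * T / 3.0))
    return 1.0 - p


def flag_ht(
    observed_identity: float,
    T: float,
    rate: float = DEFAULT_RATE,
    margin: float = 0.10,
    taxon_pair: tuple[str, str] = ("a", "b"),
) -> HTEvidence:
    """Flag a taxon pair when observed element identity exceeds the
    vertical-descent expectation by more than ``margin`` (strict)."""
    if not 0.0 <= observed_identity <= 1.0:
        raise ValueError("observed_identity must be within [0, 1]")
    expected = expected_vertical_identity(T, rate)
    return HTEvidence(
        taxon_pair=taxon_pair,
        observed_identity=observed_identity,
        divergence_time=T,
        assumed_rate=rate,
        expected_identity=expected,
        margin=margin,
        flagged=observed_identity > expected + margin,
    )


def ht_scan(
    elements: dict[str, NucleotideSequence],
    host_tree: PhyloTree,
    rate: float = 1.0,
    margin: float = 0.10,
) -> list[HTEvidence]:
    """Screen every taxon pair for horizontal-transfer evidence.

    ``elements`` maps taxon name -> that taxon's element copy.  Host
    divergence for a pair is half the tree path length between the two
    taxa, in the tree's branch-length units; with the default
    ``rate=1`` those units are substitutions/site/lineage.
    """
    names, mat = host_tree.leaf_distance_matrix()
    index = {n: i for i, n in enumerate(names)}
    missing = set(elements) - set(names)
    if missing:
        raise ValueError(f"taxa not in host tree: {sorted(missing)}")
    out: list[HTEvidence] = []
    for a, b in combinations(sorted(elements), 2):
        pair = global_align(
            elements[a].residues, elements[b].residues, a_id=a, b_id=b
        )
        obs = identity_excluding_indels(pair)
        T = mat[index[a], index[b]] / 2.0
        out.append(flag_ht(obs, T, rate=rate, margin=margin, taxon_pair=(a, b)))
    return out


def write_ht_evidence_tsv(records: Sequence[HTEvidence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "taxon_a\ttaxon_b\tobserved_identity\tdivergence_time\trate\t"
            "expected_identity\tmargin\tflagged\n"
        )
        for r in records:
            fh.write(
                f"{r.taxon_pair[0]}\t{r.taxon_pair[1]}\t{r.observed_identity:.4f}\t"
                f"{r.divergence_time:g}\t{r.assumed_rate:g}\t"
                f"{r.expected_identity:.4f}\t{r.margin:g}\t{r.flagged}\n"
            )


def write_occupancy_tsv(calls: Sequence[OccupancyCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tstatus\tinsert_length_estimate\tevidence\n")
        for c in calls:
            ev = ";".join(
                f"{iv.seq_id}:{iv.start}-{iv.end}({iv.strand})" for iv in c.evidence
            )
            est = "" if c.insert_length_estimate is None else c.insert_length_estimate
            fh.write(f"{c.site_id}\t{c.status}\t{est}\t{ev}\n")


# ---------------------------------------------------------------------------
# Dollo loss counting
# ---------------------------------------------------------------------------

def dollo_loss_count(
    pam: PresenceAbsenceMatrix, host_tree: PhyloTree, element: str
) -> int:
    """Minimum losses explaining a presence pattern under single-gain
    (Dollo) parsimony, with the gain at the MRCA of the presence taxa.

    A loss is a maximal subtree below the gain node containing no
    presence taxon.
    """
    present = set(pam.present_taxa(element))
    if not present:
        raise ValueError(f"element {element!r} absent from every taxon")
    tree_taxa = set(host_tree.leaf_names)
    if not present <= tree_taxa:
        raise ValueError("presence taxa missing from host tree")
    mrca = _mrca(host_tree.root, present)

    def count(node: TreeNode) -> int:
        leaves = {l.name for l in node.leaves()}
        if not leaves & present:
            return 1  # one loss covers this whole subtree
        if node.is_leaf():
            return 0
        return sum(count(c) for c in node.children)

    return count(mrca)


def _mrca(root: TreeNode, taxa: set[str]) -> TreeNode:
    node = root
    while True:
        if node.is_leaf():
            return node
        containing = [
            c for c in node.children
            if taxa <= {l.name for l in c.leaves()}
        ]
        if len(containing) == 1:
            node = containing[0]
        else:
            return node
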