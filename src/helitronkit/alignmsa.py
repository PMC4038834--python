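"""Global pairwise alignment, progressive multiple alignment, identity
excluding indels, and consensus construction.

Identity between two aligned rows is computed over columns in which
neither row has a gap ("excluding indels"): matches divided by ungapped
columns.  This is the statistic reported throughout for inter-copy and
copy-to-consensus similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .seqcore import IUPAC_FOR_SET, NucleotideSequence


@dataclass(frozen=True)
class AlignedPair:
    """A gapped pairwise alignment of two sequences."""

    a_id: str
    b_id: str
    a_row: str
    b_row: str

    def __post_init__(self) -> None:
        if len(self.a_row) != len(self.b_row):
            raise ValueError("aligned rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.a_row)

    def degapped(self) -> tuple[str, str]:
        return self.a_row.replace("-", ""), self.b_row.replace("-", "")


@dataclass(frozen=True)
class MultipleAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must correspond")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("all rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def pair(self, i: int, j: int) -> AlignedPair:
        return AlignedPair(self.ids[i], self.ids[j], self.rows[i], self.rows[j])


@dataclass(frozen=True)
class ConsensusResult:
    residues: str
    support: tuple[float, ...]  # per retained column, fraction backing the call


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float,
             end_gap_free: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    if end_gap_free:
        aligner.end_gap_score = 0
    return aligner


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
    a_id: str = "a",
    b_id: str = "b",
    end_gap_free: bool = False,
) -> AlignedPair:
    """Optimal Needleman-Wunsch global alignment with affine gaps.

    A gap of length L scores ``gap_open + L * gap_extend``.  With
    ``end_gap_free`` terminal gaps in either sequence are not penalised
    (overlap alignment).
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    aligner = _aligner(match, mismatch, gap_open, gap_extend, end_gap_free)
    aln = aligner.align(a, b)[0]
    return AlignedPair(a_id, b_id, str(aln[0]), str(aln[1]))


def identity_excluding_indels(p: AlignedPair) -> float:
    """Matches over columns with no gap in either row."""
    matches = 0
    ungapped = 0
    for x, y in zip(p.a_row, p.b_row):
        if x != "-" and y != "-":
            ungapped += 1
            if x == y:
                matches += 1
    if ungapped == 0:
        raise ValueError(
            f"no gap-free columns between {p.a_id!r} and {p.b_id!r}"
        )
    return matches / ungapped


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

_ALPHA = "ACGT-"
_ALPHA_INDEX = {c: i for i, c in enumerate(_ALPHA)}


def _kmer_distance_matrix(seqs: Sequence[str], k: int = 6) -> np.ndarray:
    """Fractional shared-k-mer distance used only for the guide tree."""
    sets = [frozenset(s[i : i + k] for i in range(max(0, len(s) - k + 1))) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            shared = len(sets[i] & sets[j]) / denom if denom else 0.0
            d[i, j] = d[j, i] = 1.0 - shared
    return d


def _profile(rows: Sequence[str]) -> np.ndarray:
    """Column frequency profile over A, C, G, T (gaps and degenerate
    codes contribute nothing; frequencies are per aligned row)."""
    ncol = len(rows[0])
    prof = np.zeros((ncol, 4))
    for row in rows:
        for j, c in enumerate(row):
            idx = _ALPHA_INDEX.get(c)
            if idx is not None and idx < 4:
                prof[j, idx] += 1.0
    return prof / len(rows)


def _align_profiles(
    rows_a: Sequence[str],
    rows_b: Sequence[str],
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Affine-gap DP over column profiles; returns gapped row groups."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    # expected score of aligning column i of A with column j of B
    sub = match * (pa @ pb.T) + mismatch * (
        pa.sum(axis=1)[:, None] * pb.sum(axis=1)[None, :] - pa @ pb.T
    )
    neg = -1e18
    open_cost = gap_open + gap_extend
    M = np.full((la + 1, lb + 1), neg)
    X = np.full((la + 1, lb + 1), neg)  # gap in B (consumes A)
    Y = np.full((la + 1, lb + 1), neg)  # gap in A (consumes B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = open_cost + (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0, j] = open_cost + (j - 1) * gap_extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + sub[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] + open_cost, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + open_cost)
            Y[i, j] = max(M[i, j - 1] + open_cost, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + open_cost)
    # traceback, preferring diagonal, then gap-in-B, then gap-in-A
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append("|")
            out_b.append("|")
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 and i > 0:
            out_a.append("|")
            out_b.append("-")
            cands = [M[i - 1, j] + open_cost, X[i - 1, j] + gap_extend,
                     Y[i - 1, j] + open_cost]
            i -= 1
            state = int(np.argmax(cands))
        elif state == 2 and j > 0:
            out_a.append("-")
            out_b.append("|")
            cands = [M[i, j - 1] + open_cost, X[i, j - 1] + open_cost,
                     Y[i, j - 1] + gap_extend]
            j -= 1
            state = int(np.argmax(cands))
        elif i > 0:
            state = 1
            continue
        else:
            state = 2
            continue
    ops_a = "".join(reversed(out_a))
    ops_b = "".join(reversed(out_b))

    def expand(rows: Sequence[str], ops: str) -> list[str]:
        result = []
        for row in rows:
            buf = []
            pos = 0
            for op in ops:
                if op == "|":
                    buf.append(row[pos])
                    pos += 1
                else:
                    buf.append("-")
            result.append("".join(buf))
        return result

    return expand(rows_a, ops_a), expand(rows_b, ops_b)


def progressive_msa(
    seqs: Sequence[NucleotideSequence],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
    guide_k: int = 6,
) -> MultipleAlignment:
    """Progressive multiple alignment.

    A UPGMA guide tree is built from shared-k-mer distances (k=6 by
    default); groups are merged bottom-up by affine-gap profile-profile
    alignment.  Deterministic for a fixed input order.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa requires at least 2 sequences")
    if len(seqs) == 2:
        pair = global_align(
            seqs[0].residues, seqs[1].residues, match, mismatch, gap_open,
            gap_extend, a_id=seqs[0].id, b_id=seqs[1].id,
        )
        return MultipleAlignment((pair.a_id, pair.b_id), (pair.a_row, pair.b_row))
    d = _kmer_distance_matrix([s.residues for s in seqs], guide_k)
    tree = to_tree(linkage(squareform(d, checks=False), method="average"))

    def merge(node) -> tuple[list[int], list[str]]:
        if node.is_leaf():
            return [node.id], [seqs[node.id].residues]
        ids_l, rows_l = merge(node.get_left())
        ids_r, rows_r = merge(node.get_right())
        rows_l, rows_r = _align_profiles(
            rows_l, rows_r, match, mismatch, gap_open, gap_extend
        )
        return ids_l + ids_r, rows_l + rows_r

    order, rows = merge(tree)
    # restore input order
    by_index = dict(zip(order, rows))
    ids = tuple(s.id for s in seqs)
    return MultipleAlignment(ids, tuple(by_index[i] for i in range(len(seqs))))


def build_consensus(msa: MultipleAlignment, min_fraction: float = 0.5) -> ConsensusResult:
    """Majority consensus with IUPAC codes for ties.

    Columns gapped in more than half the rows are dropped.  In retained
    columns the most frequent non-gap residue is called when its
    fraction (of non-gap residues) reaches ``min_fraction``; otherwise
    the IUPAC code of the set of maximally frequent residues is used.
    """
    if msa.n_rows < 2:
        raise ValueError("consensus requires at least 2 rows")
    residues: list[str] = []
    support: list[float] = []
    n = msa.n_rows
    for j in range(msa.n_columns):
        column = [row[j] for row in msa.rows]
        non_gap = [c for c in column if c != "-"]
        if len(non_gap) * 2 < n:
            continue
        counts: dict[str, int] = {}
        for c in non_gap:
            counts[c] = counts.get(c, 0) + 1
        top = max(counts.values())
        winners = sorted(c for c, v in counts.items() if v == top)
        frac = top / len(non_gap)
        if len(winners) == 1 and frac >= min_fraction:
            residues.append(winners[0])
        else:
            degeneracy = frozenset().union(
                *({w} if w in "ACGT" else set() for w in winners)
            )
            residues.append(IUPAC_FOR_SET.get(frozenset(degeneracy), "N"))
        support.append(frac)
    return ConsensusResult("".join(residues), tuple(support))


def pairwise_identity_matrix(
    seqs: Sequence[NucleotideSequence],
    end_gap_free: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Symmetric matrix of identity-excluding-indels over global alignments."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(seqs)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = global_align(
                seqs[i].residues, seqs[j].residues,
                a_id=seqs[i].id, b_id=seqs[j].id, end_gap_free=end_gap_free,
            )
            mat[i, j] = mat[j, i] = identity_excluding_indels(pair)
    return [s.id for s in seqs], mat


def write_identity_matrix(
    labels: Sequence[str], matrix: np.ndarray, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(labels) + "\n")
        for label, row in zip(labels, matrix):
            fh.write(label + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")


def write_aligned_fasta(msa: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(msa.ids, msa.rows):
            fh.write(f">{name}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


def read_aligned_fasta(path: str | Path) -> MultipleAlignment:
    ids: list[str] = []
    rows: list[str] = []
    current: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if ids:
                    rows.append("".join(current))
                ids.append(line[1:].split()[0])
                current = []
            elif line:
                current.append(line.upper())
    if ids:
        rows.append("".join(current))
    return MultipleAlignment(tuple(ids), tuple(rows))
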