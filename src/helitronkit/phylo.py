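"""Distances, neighbor-joining, bootstrap support and tree comparison.

Trees are stored as simple rooted node structures; an "unrooted" tree
is represented with a trifurcating root, as produced by
neighbor-joining.  Newick parsing is delegated to dendropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import dendropy
import numpy as np

from .alignmsa import AlignedPair, MultipleAlignment, identity_excluding_indels


class SaturationError(ValueError):
    """Raised when a distance correction is undefined (log of <= 0)."""


@dataclass
class TreeNode:
    """A node of a phylogenetic tree.

    ``length`` is the branch length of the edge above this node;
    ``support`` is the bootstrap percentage of that edge (internal
    edges only).
    """

    name: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def preorder(self) -> list["TreeNode"]:
        out = [self]
        for child in self.children:
            out.extend(child.preorder())
        return out


@dataclass
class PhyloTree:
    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalised as the leaf set
        on the child side of an internal edge, re-expressed as the side
        not containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names)
        anchor = min(all_leaves)
        parts: set[frozenset[str]] = set()
        for node in self.root.preorder():
            if node is self.root or node.is_leaf():
                continue
            side = frozenset(leaf.name for leaf in node.leaves())
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            if anchor in side:
                side = all_leaves - side
            parts.add(side)
        return parts

    def internal_edges(self) -> list[TreeNode]:
        """Nodes whose parent edge is an internal (support-bearing) edge."""
        all_leaves = frozenset(self.leaf_names)
        out = []
        for node in self.root.preorder():
            if node is self.root or node.is_leaf():
                continue
            side = frozenset(leaf.name for leaf in node.leaves())
            if len(side) >= 2 and len(all_leaves - side) >= 2:
                out.append(node)
        return out

    def leaf_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Path-length distances between all leaves."""
        names: list[str] = []
        depth: dict[int, float] = {}
        paths: dict[str, list[int]] = {}

        def walk(node: TreeNode, ancestors: list[int], d: float) -> None:
            depth[id(node)] = d
            anc = ancestors + [id(node)]
            if node.is_leaf():
                names.append(node.name)
                paths[node.name] = anc
            for child in node.children:
                walk(child, anc, d + child.length)

        walk(self.root, [], 0.0)
        n = len(names)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pi, pj = paths[names[i]], paths[names[j]]
                shared = 0
                for a, b in zip(pi, pj):
                    if a == b:
                        shared += 1
                    else:
                        break
                lca = pi[shared - 1]
                d = depth[id_leaf(paths, names[i])] + depth[id_leaf(paths, names[j])] - 2 * depth[lca]
                mat[i, j] = mat[j, i] = d
        return names, mat


def id_leaf(paths: dict[str, list[int]], name: str) -> int:
    return paths[name][-1]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _gap_free_columns(p: AlignedPair) -> tuple[str, str]:
    a = []
    b = []
    for x, y in zip(p.a_row, p.b_row):
        if x != "-" and y != "-":
            a.append(x)
            b.append(y)
    return "".join(a), "".join(b)


def p_distance(p: AlignedPair) -> float:
    """Proportion of differing gap-free columns (1 - identity)."""
    return 1.0 - identity_excluding_indels(p)


def tn93_distance(p: AlignedPair) -> float:
    """Tamura-Nei (1993) distance from an aligned pair.

    Transitions within purines (A<->G) and within pyrimidines (C<->T)
    are corrected separately from transversions, using the empirical
    base frequencies of the pair (gap columns excluded, pairwise
    deletion).  Raises :class:`SaturationError` when the correction's
    logarithms are undefined.
    """
    a, b = _gap_free_columns(p)
    n = len(a)
    if n == 0:
        raise ValueError("no gap-free columns")
    freq = {c: 0.0 for c in "ACGT"}
    for s in (a, b):
        for c in s:
            if c in freq:
                freq[c] += 1.0
    total = sum(freq.values())
    if total == 0:
        raise ValueError("no unambiguous residues")
    gA, gC, gG, gT = (freq[c] / total for c in "ACGT")
    gR, gY = gA + gG, gC + gT

    p1 = p2 = q = 0
    for x, y in zip(a, b):
        if x == y:
            continue
        pair = {x, y}
        if pair == {"A", "G"}:
            p1 += 1
        elif pair == {"C", "T"}:
            p2 += 1
        else:
            q += 1
    P1, P2, Q = p1 / n, p2 / n, q / n
    if P1 == 0 and P2 == 0 and Q == 0:
        return 0.0
    if gR == 0 or gY == 0 or gA * gG == 0 and P1 > 0 or gC * gT == 0 and P2 > 0:
        raise SaturationError("degenerate base composition for TN93")

    k1 = 2 * gA * gG / gR if gA * gG > 0 else 0.0
    k2 = 2 * gC * gT / gY if gC * gT > 0 else 0.0
    k3 = 2 * (gR * gY - (gA * gG * gY / gR if gR > 0 else 0.0)
              - (gC * gT * gR / gY if gY > 0 else 0.0))
    w1 = 1 - P1 / k1 - Q / (2 * gR) if k1 > 0 else 1.0
    w2 = 1 - P2 / k2 - Q / (2 * gY) if k2 > 0 else 1.0
    w3 = 1 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError("TN93 distance saturated")
    d = -(k1 * math.log(w1) if k1 > 0 else 0.0) \
        - (k2 * math.log(w2) if k2 > 0 else 0.0) \
        - k3 * math.log(w3)
    return d


def distance_matrix_from_msa(
    msa: MultipleAlignment, model: str = "p"
) -> DistanceMatrix:
    """Pairwise distances from an MSA with pairwise deletion of gaps."""
    fn = {"p": p_distance, "tn93": tn93_distance}[model]
    n = msa.n_rows
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn(msa.pair(i, j))
    return DistanceMatrix(tuple(msa.ids), values)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Produces an unrooted tree (trifurcating root).  Negative branch
    lengths are clamped to zero with the deficit moved to the sister
    edge.  Ties in the Q matrix are broken by the smallest
    representative leaf label of each cluster.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=label) for label in D.labels]
    reps: list[str] = list(D.labels)  # tie-break representative per cluster
    d = D.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                qv = (m - 2) * d[i, j] - sums[i] - sums[j]
                pair_reps = tuple(sorted((reps[i], reps[j])))
                key = (qv, pair_reps)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (len(active) - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        # reuse slot i for the new cluster
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[i, k] = d[k, i] = max(dk, 0.0)
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, l in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(l, 0.0)
    order = sorted((i, j, k), key=lambda x: reps[x])
    root = TreeNode(children=[nodes[x] for x in order])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

TreeBuilder = Callable[[DistanceMatrix], PhyloTree]


def _default_builder(model: str) -> TreeBuilder:
    def build(D: DistanceMatrix) -> PhyloTree:
        return neighbor_joining(D)

    return build


def bootstrap(
    msa: MultipleAlignment,
    tree_builder: Optional[TreeBuilder] = None,
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "p",
) -> PhyloTree:
    """Column-resampling bootstrap.

    Builds the point-estimate tree from the full alignment, then
    resamples columns with replacement ``n_reps`` times and records,
    for every internal bipartition of the point tree, the percentage of
    replicate trees containing it.  Reproducible for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if tree_builder is None:
        tree_builder = lambda D: neighbor_joining(D)

    def matrix_from_rows(rows: Sequence[str]) -> DistanceMatrix:
        sub = MultipleAlignment(msa.ids, tuple(rows))
        return distance_matrix_from_msa(sub, model=model)

    point = tree_builder(matrix_from_rows(msa.rows))
    target = point.bipartitions()
    counts = {bp: 0 for bp in target}

    arr = np.array([list(row) for row in msa.rows])
    rng = np.random.default_rng(seed)
    ncol = msa.n_columns
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rows = ["".join(r) for r in arr[:, idx]]
        rep_tree = tree_builder(matrix_from_rows(rows))
        rep_parts = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_parts:
                counts[bp] += 1

    all_leaves = frozenset(point.leaf_names)
    anchor = min(all_leaves)
    for node in point.internal_edges():
        side = frozenset(leaf.name for leaf in node.leaves())
        if anchor in side:
            side = all_leaves - side
        node.support = 100.0 * counts[side] / n_reps
    return point


# ---------------------------------------------------------------------------
# newick i/o and comparison
# ---------------------------------------------------------------------------

def to_newick(t: PhyloTree, support_threshold: float = 50.0) -> str:
    """Newick with branch lengths; supports below the threshold omitted."""

    def render(node: TreeNode) -> str:
        if node.is_leaf():
            return f"{node.name}:{node.length:g}"
        inner = ",".join(render(c) for c in node.children)
        label = ""
        if node.support is not None and node.support >= support_threshold:
            label = f"{node.support:g}"
        return f"({inner}){label}:{node.length:g}"

    inner = ",".join(render(c) for c in t.root.children)
    return f"({inner});"


def write_newick(t: PhyloTree, path: str | Path, support_threshold: float = 50.0) -> None:
    Path(path).write_text(to_newick(t, support_threshold) + "\n")


def read_newick(text_or_path: str | Path) -> PhyloTree:
    """Parse newick (string or file path) via dendropy."""
    text = str(text_or_path)
    if "(" not in text:
        text = Path(text_or_path).read_text()
    dtree = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
            length=dnode.edge.length if dnode.edge.length is not None else 0.0,
        )
        if dnode.label is not None and not dnode.is_leaf():
            try:
                node.support = float(dnode.label)
            except ValueError:
                pass
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return PhyloTree(convert(dtree.seed_node))


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Number of non-trivial bipartitions present in exactly one tree."""
    if set(t1.leaf_names) != set(t2.leaf_names):
        raise ValueError("trees must share the same leaf set")
    return len(t1.bipartitions() ^ t2.bipartitions())


def write_distance_matrix_phylip(D: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(D.labels)}\n")
        for label, row in zip(D.labels, D.values):
            fh.write(f"{label:<10s} " + " ".join(f"{v:.6f}" for v in row) + "\n")
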