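"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's implementation paths: plain
Gotoh dynamic programming for alignment scores, exhaustive enumeration
for inverted repeats and Dollo loss placements, and a directly coded
closed form for the TN93 distance.

Gap convention everywhere: a gap of length L costs open + L * extend.
"""

from __future__ import annotations

import math
from itertools import combinations

NEG = float("-inf")


def global_score(a: str, b: str, match=1.0, mismatch=-1.0,
                 gap_open=-2.0, gap_extend=-1.0) -> float:
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open + gap_extend,
                          X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open + gap_extend,
                          Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def local_score(a: str, b: str, match=1.0, mismatch=-1.0,
                gap_open=-2.0, gap_extend=-1.0) -> float:
    n, m = len(a), len(b)
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open + gap_extend,
                          X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open + gap_extend,
                          Y[i][j - 1] + gap_extend)
            best = max(best, M[i][j])
    return best


_RC = str.maketrans("ACGT", "TGCA")


def enumerate_inverted_repeats(region: str, arm_min: int, arm_max: int,
                               loop_min: int, loop_max: int,
                               max_mismatch: int):
    """All (arm, mismatches, right_end, start, loop) inverted repeats."""
    out = []
    for arm in range(arm_min, arm_max + 1):
        for loop in range(loop_min, loop_max + 1):
            total = 2 * arm + loop
            for start in range(0, len(region) - total + 1):
                left = region[start : start + arm]
                right = region[start + arm + loop : start + total]
                rc = right.translate(_RC)[::-1]
                mism = sum(1 for x, y in zip(left, rc) if x != y)
                if mism <= max_mismatch:
                    out.append((arm, mism, start + total, start, loop))
    return out


def best_inverted_repeat(region: str, arm_min=6, arm_max=12, loop_min=2,
                         loop_max=8, max_mismatch=1):
    """Best inverted repeat under (arm desc, mismatches asc, right-end
    desc) ranking, or None."""
    cands = enumerate_inverted_repeats(
        region, arm_min, arm_max, loop_min, loop_max, max_mismatch
    )
    if not cands:
        return None
    return max(cands, key=lambda c: (c[0], -c[1], c[2], c[3], c[4]))


def tn93_closed_form(a: str, b: str) -> float:
    """TN93 distance written directly from the published closed form."""
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    n = len(pairs)
    counts = {c: 0 for c in "ACGT"}
    for x, y in pairs:
        counts[x] += 1
        counts[y] += 1
    tot = sum(counts.values())
    gA, gC, gG, gT = (counts[c] / tot for c in "ACGT")
    gR, gY = gA + gG, gC + gT
    P1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / n
    P2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / n
    Q = sum(1 for x, y in pairs
            if x != y and {x, y} not in ({"A", "G"}, {"C", "T"})) / n
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def dollo_losses_brute(edges: dict[str, tuple], root: str,
                       present: set[str]) -> int:
    """Minimum Dollo losses by exhaustive enumeration over loss-edge sets.

    ``edges`` maps node id -> tuple of child ids (leaves have empty
    tuples); leaf ids are taxon names.  The gain sits at the MRCA of
    the presence taxa; every subset of edges below it is tried as loss
    placements.
    """

    def leaves_under(node: str) -> set[str]:
        if not edges[node]:
            return {node}
        out: set[str] = set()
        for c in edges[node]:
            out |= leaves_under(c)
        return out

    # MRCA: deepest node whose subtree contains all presence taxa
    node = root
    while True:
        nxt = [c for c in edges[node] if present <= leaves_under(c)]
        if len(nxt) == 1:
            node = nxt[0]
        else:
            break
    mrca = node

    sub_edges: list[str] = []  # edges identified by their child node

    def collect(n: str) -> None:
        for c in edges[n]:
            sub_edges.append(c)
            collect(c)

    collect(mrca)
    all_leaves = leaves_under(mrca)

    best = None
    for r in range(len(sub_edges) + 1):
        if best is not None:
            break
        for losses in combinations(sub_edges, r):
            lost: set[str] = set()
            for e in losses:
                lost |= leaves_under(e)
            pattern = all_leaves - lost
            if pattern == present:
                best = r
                break
    return best
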