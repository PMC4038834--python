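"""Structural annotation of candidate Lep1-style Helitron loci.

A candidate hit is promoted to an element call by (1) refining its
boundaries to the canonical junction context — the element starts with
``TC`` immediately after a host ``A`` and ends on a ``CTRY`` tetramer
immediately before a host ``T`` — and (2) evaluating the family's
structural hallmarks: the 5'-TC / 3'-CTRY termini, a ``CTRR`` motif
near the 3' end of the acquired (species-specific) tail, a short
palindromic hairpin near the 3' terminus, precise A/T integration, and
the absence of a target-site duplication (rolling-circle insertions
create none).

All element-level coordinates (core, acquired, hairpin) are expressed
in the element's own 5'->3' orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import Align

from .search import CandidateHit, local_align
from .seqcore import (
    Interval,
    NucleotideSequence,
    extract_region,
    iupac_match,
    reverse_complement,
)

FIVE_PRIME_MOTIF = "TC"
THREE_PRIME_MOTIF = "CTRY"
ACQUIRED_END_MOTIF = "CTRR"


@dataclass(frozen=True)
class Hairpin:
    """An inverted repeat near the 3' terminus that can fold into a hairpin."""

    left_arm: Interval
    right_arm: Interval
    loop_len: int
    mismatches: int

    @property
    def arm_len(self) -> int:
        return len(self.left_arm)

    @property
    def span(self) -> int:
        return self.right_arm.end - self.left_arm.start


@dataclass(frozen=True)
class AnnotateConfig:
    flank: int = 500
    boundary_window: int = 30
    hairpin_search_window: int = 50
    hairpin_arm_min: int = 6
    hairpin_arm_max: int = 12
    hairpin_loop_min: int = 2
    hairpin_loop_max: int = 8
    hairpin_max_mismatch: int = 1
    tsd_k_min: int = 4
    tsd_k_max: int = 10
    ctrr_window: int = 15


@dataclass(frozen=True)
class Lep1Annotation:
    """A fully evaluated element call."""

    element_iv: Interval          # subject coordinates, stranded
    core_iv: Interval             # element-oriented coordinates
    acquired_iv: Optional[Interval]  # element-oriented; None when empty
    five_prime_tc: bool
    three_prime_ctry: bool
    ctrr_in_acquired: bool
    ctrr_position: Optional[int]  # element-oriented start of the CTRR match
    hairpin: Optional[Hairpin]
    junction_status: str          # "AT", "not_AT" or "undetermined"
    tsd_detected: Optional[bool]  # None when flanks unavailable
    tsd_kmer: Optional[str]
    identity_to_consensus: float
    sequence: str                 # element residues, element orientation

    @property
    def at_junction(self) -> bool:
        return self.junction_status == "AT"

    @property
    def full_length(self) -> bool:
        """All hallmarks present: TC/CTRY termini, a determinate A/T
        junction, and no target-site duplication."""
        return (
            self.five_prime_tc
            and self.three_prime_ctry
            and self.junction_status == "AT"
            and self.tsd_detected is False
        )


def detect_termini(element: str) -> tuple[bool, bool]:
    """Test the 5' prefix against TC and the 3' suffix against CTRY."""
    if len(element) < 6:
        raise ValueError("element shorter than 6 bp; termini undefined")
    return (
        iupac_match(element[:2], FIVE_PRIME_MOTIF),
        iupac_match(element[-4:], THREE_PRIME_MOTIF),
    )


def check_at_junction(upstream_flank: str, downstream_flank: str) -> bool:
    """True iff the host sequence reads ...A | element | T..."""
    if not upstream_flank or not downstream_flank:
        raise ValueError("both flanks must be non-empty")
    return upstream_flank[-1] == "A" and downstream_flank[0] == "T"


def detect_tsd(
    upstream_flank: str,
    downstream_flank: str,
    k_min: int = 4,
    k_max: int = 10,
) -> tuple[bool, Optional[str]]:
    """Scan for a duplicated host k-mer bracketing the insertion.

    Returns (found, kmer).  Flanks shorter than ``k_max`` are tested up
    to the available length, with a warning.
    """
    limit = min(len(upstream_flank), len(downstream_flank))
    if limit < k_max:
        warnings.warn(
            f"flanks shorter than k_max={k_max}; TSD scan limited to k<={limit}",
            stacklevel=2,
        )
    for k in range(min(k_max, limit), k_min - 1, -1):
        if upstream_flank[-k:] == downstream_flank[:k]:
            return True, upstream_flank[-k:]
    return False, None


def find_hairpin(
    element: str,
    search_window: int = 50,
    arm_min: int = 6,
    arm_max: int = 12,
    loop_min: int = 2,
    loop_max: int = 8,
    max_mismatch: int = 1,
    seq_id: str = "element",
) -> Optional[Hairpin]:
    """Best inverted repeat entirely within the last ``search_window`` bases.

    Ranking: longest arm, then fewest mismatches, then right-arm end
    closest to the 3' terminus.  ``None`` when no arm >= ``arm_min``
    qualifies.
    """
    if len(element) < search_window:
        raise ValueError(
            f"element ({len(element)} bp) shorter than search window {search_window}"
        )
    offset = len(element) - search_window
    region = element[offset:]
    best: Optional[tuple[int, int, int, int, int]] = None
    # (arm, -mismatches, right_end, start, loop) maximised lexicographically
    for arm in range(arm_max, arm_min - 1, -1):
        for loop in range(loop_min, loop_max + 1):
            total = 2 * arm + loop
            for start in range(0, search_window - total + 1):
                left = region[start : start + arm]
                right = region[start + arm + loop : start + total]
                mism = sum(
                    1 for x, y in zip(left, reverse_complement(right)) if x != y
                )
                if mism > max_mismatch:
                    continue
                key = (arm, -mism, start + total, start, loop)
                if best is None or key > best:
                    best = key
        if best is not None and best[0] == arm:
            break
    if best is None:
        return None
    arm, neg_mism, right_end, start, loop = best
    left_iv = Interval(seq_id, offset + start, offset + start + arm)
    right_iv = Interval(
        seq_id, offset + start + arm + loop, offset + right_end
    )
    return Hairpin(left_iv, right_iv, loop, -neg_mism)


def refine_boundaries(
    hit: CandidateHit,
    subject: NucleotideSequence,
    flank: int = 500,
    window: int = 30,
    acquired_reach: int = 150,
) -> Interval:
    """Snap hit boundaries to the canonical junction context.

    The element start is the position nearest the hit 5' end (within
    ±``window``) where the element begins ``TC`` and the preceding host
    base is ``A``.  The element end is a position where the element
    ends on ``CTRY`` and the following host base is ``T``; because a
    core-consensus hit typically stops short of the species-specific
    acquired tail, the end is searched up to ``acquired_reach`` bases
    downstream of the hit as well, and candidate ends are ranked by
    hallmark support (a ``CTRR`` motif just upstream, then a perfect
    hairpin arm ending nearby) before proximity to the hit.  If either
    anchor is missing the raw hit boundaries are returned.
    """
    iv = hit.subject_iv
    if iv.end > len(subject):
        raise ValueError(
            f"hit interval [{iv.start}, {iv.end}) outside subject {subject.id!r}"
        )
    s = subject.residues
    length = len(s)
    if iv.strand == "-":
        s = reverse_complement(s)
        hs, he = length - iv.end, length - iv.start
    else:
        hs, he = iv.start, iv.end

    start = _nearest_start(s, hs, window)
    end = _best_end(s, he, window, acquired_reach)
    if start is None or end is None or end - start < 6:
        return iv

    if iv.strand == "-":
        return Interval(iv.seq_id, length - end, length - start, "-")
    return Interval(iv.seq_id, start, end, "+")


def _nearest_start(s: str, anchor: int, window: int) -> Optional[int]:
    best = None
    for p in range(max(1, anchor - window), min(len(s) - 2, anchor + window) + 1):
        if s[p : p + 2] == "TC" and s[p - 1] == "A":
            if best is None or (abs(p - anchor), p) < (abs(best - anchor), best):
                best = p
    return best


def _best_end(s: str, anchor: int, window: int, reach: int) -> Optional[int]:
    lo = max(4, anchor - window)
    hi = min(len(s) - 1, anchor + window + reach)
    best = None  # (-hallmark_score, distance, q)
    for q in range(lo, hi + 1):
        if s[q] != "T" or not iupac_match(s[q - 4 : q], THREE_PRIME_MOTIF):
            continue
        score = _end_hallmark_score(s, q)
        if score == 0 and abs(q - anchor) > window:
            # far candidates need hallmark support; otherwise any chance
            # CTRY|T in the downstream reach would hijack the terminus
            continue
        key = (-score, abs(q - anchor), q)
        if best is None or key < best:
            best = key
    return None if best is None else best[2]


def _end_hallmark_score(s: str, q: int) -> int:
    """Hallmark support for an element end at ``q``: +1 for a CTRR
    tetramer in the ~15 bases before the terminal CTRY, +1 for a
    perfect inverted repeat (arm >= 8) ending within 25 bases."""
    score = 0
    lo = max(0, q - 19)
    if any(
        iupac_match(s[i : i + 4], ACQUIRED_END_MOTIF) for i in range(lo, q - 6)
    ):
        score += 1
    if _has_perfect_arm(s, max(0, q - 45), q - 4):
        score += 1
    return score


def _has_perfect_arm(s: str, lo: int, hi: int, arm_min: int = 8,
                     arm_max: int = 12, loop_min: int = 2, loop_max: int = 8) -> bool:
    region = s[lo:hi]
    for arm in range(arm_max, arm_min - 1, -1):
        for loop in range(loop_min, loop_max + 1):
            total = 2 * arm + loop
            for start in range(0, len(region) - total + 1):
                left = region[start : start + arm]
                right = region[start + arm + loop : start + total]
                if left == reverse_complement(right):
                    return True
    return False


def delineate_acquired(
    element: str,
    consensus: NucleotideSequence,
    ctrr_window: int = 15,
    min_identity: float = 0.60,
    seq_id: str = "element",
) -> tuple[Interval, Optional[Interval], bool, Optional[int], float]:
    """Split an element into conserved core and 3' acquired tail.

    The core is the element span covered by the best overlap alignment
    to the family consensus (element overhangs free, consensus end gaps
    penalised); the acquired region is everything 3' of the core.
    Returns (core_iv, acquired_iv, ctrr_found, ctrr_position, identity),
    with identity computed over consensus-aligned columns excluding
    indel columns.
    """
    if not element:
        raise ValueError("empty element")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -1.0
    aligner.end_deletion_score = 0.0  # element overhang is free
    aln = aligner.align(element, consensus.residues)[0]
    e_row, c_row = str(aln[0]), str(aln[1])
    matches = ungapped = 0
    for x, y in zip(e_row, c_row):
        if x != "-" and y != "-":
            ungapped += 1
            if x == y:
                matches += 1
    if ungapped == 0 or matches / ungapped < min_identity:
        raise ValueError("not a Lep1 candidate: no significant consensus homology")
    identity = matches / ungapped
    blocks = aln.aligned[0]
    core_end = int(blocks[-1][1])
    core_iv = Interval(seq_id, 0, core_end)
    acquired_iv = (
        Interval(seq_id, core_end, len(element)) if core_end < len(element) else None
    )
    ctrr_found = False
    ctrr_position: Optional[int] = None
    if acquired_iv is not None:
        tail = element[acquired_iv.start : acquired_iv.end]
        lo = max(0, len(tail) - ctrr_window)
        for i in range(len(tail) - 4, lo - 1, -1):
            if iupac_match(tail[i : i + 4], ACQUIRED_END_MOTIF):
                ctrr_found = True
                ctrr_position = acquired_iv.start + i
                break
    return core_iv, acquired_iv, ctrr_found, ctrr_position, identity


def annotate_element(
    hit: CandidateHit,
    subject: NucleotideSequence,
    consensus: NucleotideSequence,
    config: AnnotateConfig = AnnotateConfig(),
) -> Lep1Annotation:
    """Compose boundary refinement and all hallmark tests for one hit."""
    element_iv = refine_boundaries(
        hit, subject, flank=config.flank, window=config.boundary_window
    )
    element = extract_region(subject, element_iv)
    five_tc, three_ctry = detect_termini(element)

    up, down = _oriented_flanks(subject, element_iv, config.flank)
    if up and down:
        junction = "AT" if check_at_junction(up, down) else "not_AT"
        if min(len(up), len(down)) >= config.tsd_k_min:
            tsd, tsd_kmer = detect_tsd(up, down, config.tsd_k_min, config.tsd_k_max)
        else:
            tsd, tsd_kmer = None, None
    else:
        warnings.warn(
            f"element at contig edge of {subject.id!r}: junction undetermined",
            stacklevel=2,
        )
        junction = "undetermined"
        tsd, tsd_kmer = None, None

    hairpin = (
        find_hairpin(
            element,
            search_window=config.hairpin_search_window,
            arm_min=config.hairpin_arm_min,
            arm_max=config.hairpin_arm_max,
            loop_min=config.hairpin_loop_min,
            loop_max=config.hairpin_loop_max,
            max_mismatch=config.hairpin_max_mismatch,
        )
        if len(element) >= config.hairpin_search_window
        else None
    )
    core_iv, acquired_iv, ctrr_found, ctrr_pos, identity = delineate_acquired(
        element, consensus, ctrr_window=config.ctrr_window
    )
    return Lep1Annotation(
        element_iv=element_iv,
        core_iv=core_iv,
        acquired_iv=acquired_iv,
        five_prime_tc=five_tc,
        three_prime_ctry=three_ctry,
        ctrr_in_acquired=ctrr_found,
        ctrr_position=ctrr_pos,
        hairpin=hairpin,
        junction_status=junction,
        tsd_detected=tsd,
        tsd_kmer=tsd_kmer,
        identity_to_consensus=identity,
        sequence=element,
    )


def _oriented_flanks(
    subject: NucleotideSequence, iv: Interval, flank: int
) -> tuple[str, str]:
    """Host flanks in element orientation (empty string at a contig edge)."""
    s = subject.residues
    left = s[max(0, iv.start - flank) : iv.start]
    right = s[iv.end : iv.end + flank]
    if iv.strand == "-":
        return reverse_complement(right), reverse_complement(left)
    return left, right


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def write_annotations_gff3(
    annotations: Sequence[Lep1Annotation], path: str | Path, source: str = "helitronkit"
) -> None:
    """GFF3 with element features and core/acquired/hairpin children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for n, ann in enumerate(annotations, 1):
            iv = ann.element_iv
            eid = f"element{n}"
            attrs = (
                f"ID={eid};full_length={str(ann.full_length).lower()};"
                f"five_prime_tc={str(ann.five_prime_tc).lower()};"
                f"three_prime_ctry={str(ann.three_prime_ctry).lower()};"
                f"junction={ann.junction_status};"
                f"identity_to_consensus={ann.identity_to_consensus:.4f}"
            )
            fh.write(
                f"{iv.seq_id}\t{source}\tmobile_genetic_element\t{iv.start + 1}\t"
                f"{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for name, child in (("core", ann.core_iv), ("acquired", ann.acquired_iv)):
                if child is None:
                    continue
                g_start, g_end = _element_to_genome(iv, child.start, child.end)
                fh.write(
                    f"{iv.seq_id}\t{source}\t{name}\t{g_start + 1}\t{g_end}\t.\t"
                    f"{iv.strand}\t.\tID={eid}.{name};Parent={eid}\n"
                )
            if ann.hairpin is not None:
                g_start, g_end = _element_to_genome(
                    iv, ann.hairpin.left_arm.start, ann.hairpin.right_arm.end
                )
                fh.write(
                    f"{iv.seq_id}\t{source}\thairpin_loop\t{g_start + 1}\t{g_end}\t.\t"
                    f"{iv.strand}\t.\tID={eid}.hairpin;Parent={eid};"
                    f"arm_len={ann.hairpin.arm_len};loop_len={ann.hairpin.loop_len};"
                    f"mismatches={ann.hairpin.mismatches}\n"
                )


def _element_to_genome(iv: Interval, e_start: int, e_end: int) -> tuple[int, int]:
    if iv.strand == "+":
        return iv.start + e_start, iv.start + e_end
    return iv.end - e_end, iv.end - e_start


def write_annotations_tsv(
    annotations: Sequence[Lep1Annotation], path: str | Path
) -> None:
    cols = [
        "subject_id", "start", "end", "strand", "length", "full_length",
        "five_prime_tc", "three_prime_ctry", "ctrr_in_acquired", "hairpin",
        "junction", "tsd_detected", "core_len", "acquired_len",
        "identity_to_consensus",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for ann in annotations:
            iv = ann.element_iv
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        iv.seq_id, iv.start, iv.end, iv.strand, len(iv),
                        ann.full_length, ann.five_prime_tc, ann.three_prime_ctry,
                        ann.ctrr_in_acquired,
                        "-" if ann.hairpin is None
                        else f"{ann.hairpin.arm_len}/{ann.hairpin.loop_len}/{ann.hairpin.mismatches}",
                        ann.junction_status, ann.tsd_detected,
                        len(ann.core_iv),
                        0 if ann.acquired_iv is None else len(ann.acquired_iv),
                        f"{ann.identity_to_consensus:.4f}",
                    )
                )
                + "\n"
            )
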