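"""Candidate-locus discovery by seed-and-extend local alignment.

The search mirrors a conventional nucleotide homology screen: exact
k-mer seeds (both strands) are clustered into candidate loci, each
locus is verified by an optimal affine-gap local alignment, and hits
are filtered on identity and aligned length.  The default filter keeps
hits that are at least 70% identical to the query over more than
100 aligned columns.

Gap scoring convention: a gap of length ``L`` scores
``gap_open + L * gap_extend`` (so the first gapped column already pays
both the opening and one extension).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import Align

from .seqcore import Interval, NucleotideSequence, reverse_complement


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of ``a`` (query) against ``b`` (subject)."""

    a_row: str
    b_row: str
    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def n_columns(self) -> int:
        return len(self.a_row)

    @property
    def n_matches(self) -> int:
        return sum(
            1 for x, y in zip(self.a_row, self.b_row) if x == y and x != "-"
        )

    @property
    def n_ungapped_columns(self) -> int:
        return sum(
            1 for x, y in zip(self.a_row, self.b_row) if x != "-" and y != "-"
        )

    @property
    def identity(self) -> float:
        n = self.n_ungapped_columns
        if n == 0:
            raise ValueError("alignment has no ungapped columns")
        return self.n_matches / n


@dataclass(frozen=True)
class CandidateHit:
    """A filtered local-alignment match of the query in a subject."""

    query_id: str
    subject_iv: Interval
    identity: float
    aln_length: int
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")


def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float,
             mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython charges open_gap_score for the first gapped column and
    # extend_gap_score for each further one; our convention charges
    # open + extend for the first column.
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def local_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment of ``a`` against ``b``.

    Ties between co-optimal alignments are broken deterministically
    (first alignment in the aligner's traceback enumeration, which
    prefers earlier subject and query starts).
    """
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    aligner = _aligner(match, mismatch, gap_open, gap_extend, "local")
    alignments = aligner.align(a, b)
    if alignments.score <= 0:
        # the optimal local alignment is empty
        return LocalAlignment("", "", 0.0, 0, 0, 0, 0)
    aln = alignments[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    (a_blocks, b_blocks) = aln.aligned
    return LocalAlignment(
        a_row=a_row,
        b_row=b_row,
        score=aln.score,
        a_start=int(a_blocks[0][0]),
        a_end=int(a_blocks[-1][1]),
        b_start=int(b_blocks[0][0]),
        b_end=int(b_blocks[-1][1]),
    )


def _kmer_positions(s: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(s) - k + 1):
        index.setdefault(s[i : i + k], []).append(i)
    return index


def _seed_clusters(query: str, subject: str, k: int) -> list[tuple[int, int]]:
    """Cluster exact k-mer seed matches into candidate subject spans."""
    index = _kmer_positions(query, k)
    seeds: list[int] = []
    for j in range(len(subject) - k + 1):
        if subject[j : j + k] in index:
            seeds.append(j)
    clusters: list[tuple[int, int]] = []
    qlen = len(query)
    for j in seeds:
        if clusters and j - clusters[-1][1] <= qlen:
            clusters[-1] = (clusters[-1][0], j + k)
        else:
            clusters.append((j, j + k))
    return clusters


def find_candidates(
    query: NucleotideSequence,
    subjects: Sequence[NucleotideSequence],
    min_identity: float = 0.70,
    min_length: int = 100,
    k: int = 11,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> list[CandidateHit]:
    """Seed-and-extend search for the query in each subject, both strands.

    Returns hits with ``identity >= min_identity`` and
    ``aln_length > min_length`` (aligned columns, gaps included; strictly
    greater).  Overlapping hits on the same subject are merged, keeping
    the best-scoring representative.  Hits are sorted by subject id and
    position.
    """
    if len(query) < k:
        raise ValueError(f"query shorter than seed size {k}")
    hits: list[CandidateHit] = []
    qlen = len(query)
    for subject in subjects:
        sub = subject.residues
        per_subject: list[CandidateHit] = []
        for strand, q in (("+", query.residues), ("-", reverse_complement(query.residues))):
            for c_start, c_end in _seed_clusters(q, sub, k):
                w_start = max(0, c_start - qlen)
                w_end = min(len(sub), c_end + qlen)
                window = sub[w_start:w_end]
                aln = local_align(q, window, match, mismatch, gap_open, gap_extend)
                if aln.n_ungapped_columns == 0:
                    continue
                if aln.identity < min_identity or aln.n_columns <= min_length:
                    continue
                b_start = w_start + aln.b_start
                b_end = w_start + aln.b_end
                per_subject.append(
                    CandidateHit(
                        query_id=query.id,
                        subject_iv=Interval(subject.id, b_start, b_end, strand),
                        identity=aln.identity,
                        aln_length=aln.n_columns,
                        score=aln.score,
                    )
                )
        hits.extend(_merge_overlapping(per_subject))
    hits.sort(key=lambda h: (h.subject_iv.seq_id, h.subject_iv.start))
    return hits


def _merge_overlapping(hits: list[CandidateHit]) -> list[CandidateHit]:
    """Keep the best-scoring representative of each overlapping group."""
    ordered = sorted(hits, key=lambda h: (-h.score, h.subject_iv.start))
    kept: list[CandidateHit] = []
    for hit in ordered:
        if any(
            hit.subject_iv.start < other.subject_iv.end
            and other.subject_iv.start < hit.subject_iv.end
            for other in kept
        ):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: h.subject_iv.start)
    return kept


def read_hit_table(path: str | Path) -> list[CandidateHit]:
    """Read a 12-column BLAST tabular (outfmt 6) file into hits.

    Percent identities become fractions; subject coordinates become
    0-based half-open intervals with strand inferred from coordinate
    order (``sstart > send`` means minus strand).
    """
    hits: list[CandidateHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"found {len(fields)}"
                )
            qseqid, sseqid = fields[0], fields[1]
            pident = float(fields[2])
            length = int(fields[3])
            sstart, send = int(fields[8]), int(fields[9])
            bitscore = float(fields[11])
            if sstart <= send:
                iv = Interval(sseqid, sstart - 1, send, "+")
            else:
                iv = Interval(sseqid, send - 1, sstart, "-")
            hits.append(
                CandidateHit(
                    query_id=qseqid,
                    subject_iv=iv,
                    identity=pident / 100.0,
                    aln_length=length,
                    score=bitscore,
                )
            )
    return hits


def write_hits_tsv(hits: Sequence[CandidateHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tsubject_id\tstart\tend\tstrand\tidentity\taln_length\tscore\n")
        for h in hits:
            iv = h.subject_iv
            fh.write(
                f"{h.query_id}\t{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.strand}\t"
                f"{h.identity:.4f}\t{h.aln_length}\t{h.score:g}\n"
            )


def write_hits_bed(hits: Sequence[CandidateHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            iv = h.subject_iv
            name = f"{h.query_id}_hit"
            score = min(1000, int(round(h.identity * 1000)))
            fh.write(
                f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )
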