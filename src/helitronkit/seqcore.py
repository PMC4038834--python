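"""Sequence and interval primitives shared by the whole toolkit.

Conventions
-----------
* Residues are upper-case IUPAC nucleotide codes; ``U`` is normalised to
  ``T`` on ingest.
* Intervals are 0-based, half-open ``[start, end)`` with an explicit
  strand.  GenBank-style 1-based inclusive pairs (``"774-963"``, or
  ``"371-171"`` for the minus strand) are converted on ingest.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_CODES = "ACGTRYSWKMBDHVN"

#: degeneracy class of every IUPAC nucleotide code
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: inverse map: degeneracy set -> IUPAC code
IUPAC_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad alphabet, bad FASTA)."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified IUPAC nucleotide sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues))
        bad = set(self.residues) - set(IUPAC_CODES)
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.seq_id}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @classmethod
    def from_genbank(cls, seq_id: str, location: str) -> "Interval":
        """Parse a 1-based inclusive ``"a-b"`` pair; ``a > b`` means minus strand."""
        parts = location.replace("–", "-").split("-")
        if len(parts) != 2:
            raise ValueError(f"cannot parse location {location!r}")
        a, b = int(parts[0]), int(parts[1])
        if a <= b:
            return cls(seq_id, a - 1, b, "+")
        return cls(seq_id, b - 1, a, "-")

    def to_genbank(self) -> str:
        if self.strand == "+":
            return f"{self.start + 1}-{self.end}"
        return f"{self.end}-{self.start + 1}"


def normalize_residues(residues: str) -> str:
    return residues.upper().replace("U", "T")


def reverse_complement(s: str) -> str:
    """Reverse complement, handling all degenerate IUPAC codes."""
    s = normalize_residues(s)
    bad = set(s) - set(IUPAC_CODES)
    if bad:
        raise SequenceError(f"cannot complement non-IUPAC characters: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def iupac_match(s: str, pattern: str) -> bool:
    """True iff every residue of ``s`` falls in the degeneracy class of the
    corresponding pattern symbol (degenerate residues must be subsets)."""
    if len(s) != len(pattern):
        raise ValueError(f"length mismatch: |s|={len(s)} vs |pattern|={len(pattern)}")
    s = normalize_residues(s)
    pattern = normalize_residues(pattern)
    for r, p in zip(s, pattern):
        try:
            rset, pset = IUPAC_SETS[r], IUPAC_SETS[p]
        except KeyError as exc:
            raise SequenceError(f"non-IUPAC character {exc.args[0]!r}") from exc
        if not rset <= pset:
            return False
    return True


def extract_region(seq: NucleotideSequence, iv: Interval) -> str:
    """Substring for an interval; reverse-complemented on the minus strand."""
    if iv.end > len(seq):
        raise ValueError(
            f"interval [{iv.start}, {iv.end}) exceeds length {len(seq)} of {seq.id!r}"
        )
    sub = seq.residues[iv.start : iv.end]
    return reverse_complement(sub) if iv.strand == "-" else sub


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a FASTA file into :class:`NucleotideSequence` records.

    Residues are upper-cased and ``U`` becomes ``T``; any other non-IUPAC
    character raises :class:`SequenceError` naming the offending line.
    """
    path = Path(path)
    records: list[NucleotideSequence] = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise SequenceError(f"{path}:1: malformed FASTA ({exc})") from exc
    for rec in parsed:
        residues = normalize_residues(str(rec.seq))
        bad = set(residues) - set(IUPAC_CODES)
        if bad:
            line = _find_bad_line(path, bad)
            raise SequenceError(
                f"{path}:{line}: non-IUPAC character(s) {sorted(bad)} in record {rec.id!r}"
            )
        if not residues:
            raise SequenceError(f"{path}: record {rec.id!r} has no residues")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(NucleotideSequence(rec.id, residues, desc))
    if not records:
        # distinguish empty file from file without valid headers
        text = path.read_text()
        if text.strip() and not text.lstrip().startswith(">"):
            raise SequenceError(f"{path}:1: malformed FASTA (no '>' header)")
    return records


def _find_bad_line(path: Path, bad: set[str]) -> int:
    bad_up = {b.upper() for b in bad} | {b.lower() for b in bad}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.strip()) & bad_up:
                return lineno
    return 0


def write_fasta(
    records: Iterable[NucleotideSequence], path: str | Path, wrap: int = 60
) -> None:
    """Write records as FASTA, wrapping residue lines at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")


def to_seqrecord(rec: NucleotideSequence) -> SeqRecord:
    return SeqRecord(Seq(rec.residues), id=rec.id, description=rec.description)
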