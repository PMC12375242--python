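"""Alphabet handling, sequence algebra, and FASTA I/O.

All sequences are stored 5'->3' in the RNA alphabet {A, C, G, U}. DNA input
is transcribed on ingest (T -> U) and whitespace inside sequence text is
stripped, so spaced vendor-style sequence listings paste in directly.
Positions are 1-based and inclusive throughout the package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: Default forbidden motifs: a G-quadruplex seed and four consecutive weak
#: (A/U) bases.  ``M`` in a motif matches A or U.
DEFAULT_FORBIDDEN_MOTIFS = ("GGGG", "MMMM")


class Role(str, enum.Enum):
    """Functional role of a strand within the design pipeline."""

    TRIGGER = "trigger"
    SENSOR = "sensor"
    GUIDE = "guide"
    CORE = "core"
    BACKGROUND = "background"
    GENERIC = "generic"


class SequenceError(ValueError):
    """Raised for alphabet violations and malformed sequence input."""


@dataclass(frozen=True)
class NucleicSequence:
    """A named 5'->3' RNA sequence with a role tag.

    Parameters
    ----------
    id : str
        Record identifier.
    residues : str
        Sequence in the strict RNA alphabet (A/C/G/U). Validated on
        construction; use :func:`normalize_to_rna` for raw user text.
    role : Role
        Functional role tag; defaults to ``Role.GENERIC``.
    """

    id: str
    residues: str
    role: Role = Role.GENERIC

    def __post_init__(self) -> None:
        for i, ch in enumerate(self.residues, start=1):
            if ch not in RNA_ALPHABET:
                raise SequenceError(
                    f"invalid symbol {ch!r} at position {i} in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def subseq(self, start: int, end: int, id: str | None = None) -> "NucleicSequence":
        """Return the 1-based inclusive slice ``[start, end]``."""
        if not (1 <= start <= end <= len(self.residues)):
            raise SequenceError(
                f"subsequence [{start}, {end}] out of range for length {len(self)}"
            )
        return NucleicSequence(
            id=id or f"{self.id}[{start}:{end}]",
            residues=self.residues[start - 1 : end],
            role=self.role,
        )

    def with_role(self, role: Role) -> "NucleicSequence":
        return replace(self, role=role)


def normalize_to_rna(
    raw: str, id: str = "seq", role: Role = Role.GENERIC
) -> NucleicSequence:
    """Normalize raw sequence text to a strict RNA-alphabet sequence.

    Uppercases, strips whitespace, and transcribes T to U. Any symbol
    outside IUPAC A/C/G/T/U raises :class:`SequenceError` naming the
    1-based position of the first offender (counted after whitespace
    removal, i.e. the position within the actual sequence).
    """
    stripped = "".join(raw.split()).upper()
    for i, ch in enumerate(stripped, start=1):
        if ch not in "ACGTU":
            raise SequenceError(f"invalid symbol {ch!r} at position {i}")
    return NucleicSequence(id=id, residues=stripped.replace("T", "U"), role=role)


def complement_base(base: str) -> str:
    """Watson-Crick complement of a single RNA base."""
    return base.translate(_COMPLEMENT)


def is_watson_crick(a: str, b: str) -> bool:
    """True when two bases form a Watson-Crick pair (A·U or G·C)."""
    return complement_base(a) == b


def reverse_complement(s: NucleicSequence, id: str | None = None) -> NucleicSequence:
    """Watson-Crick reverse complement, returned 5'->3'.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    return NucleicSequence(
        id=id or f"{s.id}_rc",
        residues=s.residues.translate(_COMPLEMENT)[::-1],
        role=s.role,
    )


def gc_fraction(s: NucleicSequence) -> float:
    """Fraction of G+C residues, exact before any rounding.

    Rejects the empty sequence (the fraction is undefined there).
    """
    if len(s) == 0:
        raise SequenceError("gc_fraction undefined for empty sequence")
    return (s.residues.count("G") + s.residues.count("C")) / len(s)


def _motif_matches_at(residues: str, motif: str, start0: int) -> bool:
    for off, m in enumerate(motif):
        ch = residues[start0 + off]
        if m == "M":
            if ch not in "AU":
                return False
        elif ch != m:
            return False
    return True


def find_forbidden_motifs(
    s: NucleicSequence, motifs: Sequence[str] = DEFAULT_FORBIDDEN_MOTIFS
) -> list[tuple[str, int]]:
    """Locate forbidden motifs; ``M`` in a motif matches A or U.

    Every occurrence, including overlapping ones, is reported as
    ``(motif, 1-based start)``. An empty list means the sequence passes.
    """
    if not motifs:
        raise SequenceError("motif set must be non-empty")
    hits: list[tuple[str, int]] = []
    for i in range(len(s.residues)):
        for motif in motifs:
            if i + len(motif) <= len(s.residues) and _motif_matches_at(
                s.residues, motif, i
            ):
                hits.append((motif, i + 1))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def read_fasta(path: str | Path, role: Role = Role.GENERIC) -> list[NucleicSequence]:
    """Read a (multi-record) FASTA file into strict RNA sequences.

    DNA records are transcribed T->U. Empty files and duplicate record ids
    are rejected; any residue outside A/C/G/T/U is rejected at its record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    seqs: list[NucleicSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            seqs.append(normalize_to_rna(str(rec.seq), id=rec.id, role=role))
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
    return seqs


def write_fasta(
    seqs: Iterable[NucleicSequence], path: str | Path, width: int = 60
) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns (default 60)."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    writer_path = Path(path)
    with writer_path.open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
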