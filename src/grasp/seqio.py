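"""Protein sequence containers and FASTA I/O.

The search operates on two kinds of sequence objects: full-length query
proteins (:class:`ProteinSequence`) and a database of short peptide reads
(:class:`ReadSet`), typically 30-35 residues each, e.g. gene-caller output
on shotgun sequencing reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue alphabet accepted in input sequences ('X' marks ambiguity,
#: common in gene-caller output).
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class SequenceError(ValueError):
    """Raised for malformed sequence input."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid sequence (query or fixture source)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues):
            if ch not in VALID_RESIDUES:
                raise SequenceError(
                    f"sequence {self.id!r}: invalid residue {ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


class ReadSet:
    """An ordered collection of short peptide reads with unique ids.

    The position of a read in the input order is its integer index; all
    index structures refer to reads by that index.
    """

    def __init__(self, reads: Iterable[tuple[str, str]]):
        self.ids: list[str] = []
        self.seqs: list[str] = []
        seen: set[str] = set()
        for rid, seq in reads:
            if rid in seen:
                raise SequenceError(f"duplicate read id {rid!r}")
            if not seq:
                raise SequenceError(f"read {rid!r} is empty")
            seen.add(rid)
            self.ids.append(rid)
            self.seqs.append(seq)
        if not self.ids:
            raise SequenceError("read set is empty")
        self.index_of = {rid: i for i, rid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.seqs))

    @property
    def total_residues(self) -> int:
        return sum(len(s) for s in self.seqs)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReadSet":
        return cls((p.id, p.residues) for p in load_fasta(path))


def load_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a multi-record amino-acid FASTA file.

    Sequences are upper-cased and a single terminal ``*`` (stop) is
    stripped.  Any character outside the 20-letter alphabet plus ``X``
    raises :class:`SequenceError` naming the record and position.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        records.append(ProteinSequence(rec.id, seq))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, seqs: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_sequence(m: str) -> str:
    """Character-level reversal (NOT a biological reverse complement)."""
    return m[::-1]
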