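"""Chromosome sequence ingestion and normalization.

Scanning is exact-match over the {A, C, G, T, N} alphabet, so sequences are
normalized on the way in: everything is uppercased (soft-masked repeats are
scanned like any other DNA — the clustering stage, not a masking policy,
separates signal from background) and every IUPAC ambiguity code other than
A/C/G/T collapses to N, which never matches any motif.

Coordinates are 0-based, half-open everywhere inside the package; conversion
to 1-based happens only in the UCSC track writers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ChromosomeSequence",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
]

_VALID = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FastaFormatError(ValueError):
    """Raised for empty files or records with zero residues."""


class AlphabetError(ValueError):
    """Raised when a sequence contains letters outside {A, C, G, T, N}."""


@dataclass(frozen=True)
class ChromosomeSequence:
    """A single chromosome (or contig) ready for motif scanning.

    Attributes
    ----------
    name :
        Chromosome identifier, the first whitespace-delimited token of the
        FASTA header (e.g. ``"chr9"``).
    residues :
        Normalized DNA: uppercase, alphabet {A, C, G, T, N}.
    """

    name: str
    residues: str = field(repr=False)

    def __post_init__(self) -> None:
        bad = _NON_ACGTN.search(self.residues)
        if bad:
            raise AlphabetError(
                f"{self.name}: invalid residue {bad.group()!r} at position {bad.start()}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Uppercase and map any non-ACGTN letter (IUPAC codes, gaps) to N."""
    return _NON_ACGTN.sub("N", raw.upper())


def read_fasta(path: str | Path) -> list[ChromosomeSequence]:
    """Read a (possibly multi-record, wrapped, mixed-case) FASTA file.

    Returns one :class:`ChromosomeSequence` per record, in file order.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    FastaFormatError
        If the file contains no records, or a record has zero residues.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: list[ChromosomeSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = normalize_residues(str(rec.seq))
        if not residues:
            raise FastaFormatError(f"record {rec.id!r} in {path} has zero residues")
        out.append(ChromosomeSequence(name=rec.id, residues=residues))
    if not out:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return out


def write_fasta(seqs: Sequence[ChromosomeSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences back out (round-trip partner of :func:`read_fasta`)."""
    path = Path(path)
    with path.open("w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def reverse_complement(s: str) -> str:
    """Standard reverse complement over {A, C, G, T, N}; N maps to N."""
    if _NON_ACGTN.search(s.upper()):
        raise AlphabetError(f"cannot reverse-complement non-ACGTN string {s!r}")
    return str(Seq(s.upper()).reverse_complement())


def iter_fasta(path: str | Path) -> Iterator[ChromosomeSequence]:
    """Stream records one at a time (one chromosome in memory at once)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    seen = False
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = normalize_residues(str(rec.seq))
        if not residues:
            raise FastaFormatError(f"record {rec.id!r} in {path} has zero residues")
        seen = True
        yield ChromosomeSequence(name=rec.id, residues=residues)
    if not seen:
        raise FastaFormatError(f"no FASTA records found in {path}")
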