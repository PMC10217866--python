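"""Exact multi-pattern scanning: every occurrence of every motif, both strands.

Strand handling: the motif set is complement-expanded before scanning, so a
single forward pass over the chromosome finds both orientations.  A hit from
a complement-origin motif is reported on the minus strand; all other hits on
plus.  Scanning an unexpanded set is an error — it would silently miss every
minus-strand element.

All occurrences are reported, including overlapping and self-overlapping
ones: the density stage needs every composite element, and nothing in the
method restricts matches to non-overlapping placements.  Windows containing
N never match (motif words contain no N).
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import ChromosomeSequence
from .motifs import MotifSet, MotifStateError

__all__ = ["MotifHit", "find_occurrences", "dedupe_hits"]


@dataclass(frozen=True, order=True)
class MotifHit:
    """One exact occurrence of a motif: 0-based half-open interval + strand."""

    chrom: str
    start: int
    end: int
    strand: str
    motif_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid hit interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


def find_occurrences(chrom: ChromosomeSequence, ms: MotifSet) -> list[MotifHit]:
    """All exact occurrences of all motif words in *chrom*, sorted.

    Requires a complement-expanded set (see module docstring).  Output is
    sorted by (start, end, motif_id).
    """
    if not ms.complemented:
        raise MotifStateError(
            "scanning requires a complement-expanded motif set "
            "(call expand_with_complements first)"
        )
    seq = chrom.residues
    hits: list[MotifHit] = []
    for m in ms:
        strand = "-" if m.origin == "complement" else "+"
        word = m.word
        pos = seq.find(word)
        while pos != -1:
            hits.append(
                MotifHit(
                    chrom=chrom.name,
                    start=pos,
                    end=pos + len(word),
                    strand=strand,
                    motif_id=m.id,
                )
            )
            pos = seq.find(word, pos + 1)  # self-overlapping occurrences too
    hits.sort(key=lambda h: (h.start, h.end, h.motif_id))
    return hits


def dedupe_hits(hits: list[MotifHit]) -> list[MotifHit]:
    """Collapse hits sharing an identical (chrom, start, end) interval.

    A word and its reverse complement can match the same genomic interval
    (palindromes, or coincident distinct words); one genomic element must
    count once in the density.  The collapsed record keeps strand "+" if any
    member is "+", else "-"; motif ids are concatenated with ";".
    """
    out: list[MotifHit] = []
    i = 0
    n = len(hits)
    while i < n:
        j = i + 1
        group = [hits[i]]
        while (
            j < n
            and hits[j].chrom == hits[i].chrom
            and hits[j].start == hits[i].start
            and hits[j].end == hits[i].end
        ):
            group.append(hits[j])
            j += 1
        if len(group) == 1:
            out.append(group[0])
        else:
            strand = "+" if any(h.strand == "+" for h in group) else "-"
            out.append(
                MotifHit(
                    chrom=group[0].chrom,
                    start=group[0].start,
                    end=group[0].end,
                    strand=strand,
                    motif_id=";".join(h.motif_id for h in group),
                )
            )
        i = j
    return out
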