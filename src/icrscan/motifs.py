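"""Motif sets: the ZFP57 hexamer, MLL morphemes, and their composite overlaps.

The method scans chromosomes for two word sets: the ZFP57 binding-site
hexamer TGCCGC (with its reverse complement GCGGCA), and the "ZFBS-morph
overlaps" — composite words in which the hexamer and a CpG-rich MLL1/MLL2
morpheme occupy overlapping positions.  Because the overlaps carry two or
more CpG dinucleotides they are far rarer along chromosomal DNA than the
hexamer alone, which is what makes their clusters informative.

This module represents motif files (one word per line), expands a set with
reverse complements so that a single forward scanning pass covers both
strands, and generates the composite overlap words from a hexamer set and a
morpheme set by enumerating every letter-compatible overlapping placement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from .genome_io import reverse_complement

__all__ = [
    "Motif",
    "MotifSet",
    "load_motif_file",
    "expand_with_complements",
    "generate_overlap_motifs",
    "validate_overlap_set",
    "cpg_count",
    "packaged_overlap_set",
]

_WORD_RE = re.compile(r"^[ACGT]+$")

ORIGINS = ("zfbs", "morpheme", "overlap", "complement")


class MotifError(ValueError):
    pass


class MotifAlphabetError(MotifError):
    pass


class DuplicateMotifError(MotifError):
    pass


class MotifStateError(MotifError):
    """Complement expansion applied twice, or a scan run on an unexpanded set."""


def cpg_count(word: str) -> int:
    """Number of CG dinucleotides in *word* (CpG sites of the forward strand)."""
    return word.count("CG")


@dataclass(frozen=True)
class Motif:
    """A named exact DNA word.

    ``origin`` records where the word came from: a ZFP57 binding site
    (``zfbs``), an MLL morpheme (``morpheme``), a generated composite
    (``overlap``), or the reverse complement of one of those
    (``complement``, with ``source`` naming the original motif).
    """

    id: str
    word: str
    origin: str
    source: str | None = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise MotifError(f"unknown motif origin {self.origin!r}")
        if len(self.word) < 4:
            raise MotifError(f"motif {self.id!r}: word shorter than 4 bases")
        if not _WORD_RE.match(self.word):
            raise MotifAlphabetError(
                f"motif {self.id!r}: word {self.word!r} contains letters outside ACGT"
            )

    def __len__(self) -> int:
        return len(self.word)


@dataclass(frozen=True)
class MotifSet:
    """An ordered collection of motifs with unique words.

    ``complemented`` records whether reverse complements have been added;
    scanning requires an expanded set so that minus-strand occurrences are
    found by the same forward pass.
    """

    motifs: tuple[Motif, ...]
    complemented: bool = False

    def __post_init__(self) -> None:
        words = [m.word for m in self.motifs]
        if len(set(words)) != len(words):
            dupes = sorted({w for w in words if words.count(w) > 1})
            raise DuplicateMotifError(f"duplicate motif words: {', '.join(dupes)}")
        if self.complemented:
            wordset = set(words)
            for w in wordset:
                if reverse_complement(w) not in wordset:
                    raise MotifStateError(
                        f"set marked complemented but {w!r} lacks its reverse complement"
                    )

    def __iter__(self) -> Iterator[Motif]:
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(m.word for m in self.motifs)

    def by_word(self, word: str) -> Motif:
        for m in self.motifs:
            if m.word == word:
                return m
        raise KeyError(word)


def load_motif_file(path: str | Path) -> MotifSet:
    """Load a plain-text motif file: one word per line, optional ``id<TAB>word``.

    Lines starting with ``#`` are comments; blank lines are skipped.  Words
    are uppercased and validated against {A, C, G, T}; duplicates are
    rejected.  The returned set is *not* complement-expanded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"motif file not found: {path}")
    motifs: list[Motif] = []
    seen: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                mid, word = line.split("\t", 1)
                mid, word = mid.strip(), word.strip()
            else:
                mid, word = line, line
            word = word.upper()
            if not _WORD_RE.match(word):
                raise MotifAlphabetError(
                    f"{path}:{lineno}: motif word {word!r} contains letters outside ACGT"
                )
            if word in seen:
                raise DuplicateMotifError(
                    f"{path}:{lineno}: duplicate motif word {word!r} "
                    f"(first seen at line {seen[word]})"
                )
            seen[word] = lineno
            motifs.append(Motif(id=mid.upper() if mid == line else mid, word=word, origin="zfbs"))
    return MotifSet(motifs=tuple(motifs), complemented=False)


def with_origin(ms: MotifSet, origin: str) -> MotifSet:
    """Return a copy of *ms* with every motif re-tagged with *origin*."""
    return MotifSet(
        motifs=tuple(replace(m, origin=origin) for m in ms.motifs),
        complemented=ms.complemented,
    )


def expand_with_complements(ms: MotifSet) -> MotifSet:
    """Add the reverse complement of every word, deduplicated.

    Palindromic words appear once.  Added motifs record ``origin="complement"``
    and the id of their source, which is how the scanner later assigns strand.
    """
    if ms.complemented:
        raise MotifStateError("motif set is already complement-expanded")
    out = list(ms.motifs)
    words = {m.word for m in ms.motifs}
    for m in ms.motifs:
        rc = reverse_complement(m.word)
        if rc not in words:
            words.add(rc)
            out.append(Motif(id=f"{m.id}_rc", word=rc, origin="complement", source=m.id))
    return MotifSet(motifs=tuple(out), complemented=True)


def _merge_at_offset(z: str, m: str, offset: int) -> str | None:
    """Merge *m* placed at *offset* relative to *z* (z at 0) if letters agree.

    Returns the merged word (shortest superstring for this placement) or
    None when the overlapping letters disagree.
    """
    lo = min(0, offset)
    hi = max(len(z), offset + len(m))
    merged = []
    for pos in range(lo, hi):
        zc = z[pos] if 0 <= pos < len(z) else None
        mc = m[pos - offset] if 0 <= pos - offset < len(m) else None
        if zc is not None and mc is not None and zc != mc:
            return None
        merged.append(zc if zc is not None else mc)  # type: ignore[arg-type]
    return "".join(merged)


def generate_overlap_motifs(
    zfbs: MotifSet, morphemes: MotifSet, min_overlap: int = 1
) -> MotifSet:
    """Generate composite ZFBS-morph overlap words.

    For every ZFBS word ``z`` and morpheme word ``m``, every placement of
    ``m`` relative to ``z`` whose overlapping region spans at least
    *min_overlap* bases and agrees letter-for-letter yields the shortest
    superstring of the pair.  Containment counts as overlap (the contained
    word's full length).  Merged words carrying fewer than two CpG
    dinucleotides are excluded — the defining property of these composite
    elements is their CpG richness.

    Provenance: each distinct merged word keeps every ``(z_id, m_id, offset)``
    derivation in its id, joined by ``|``.
    """
    if zfbs.complemented or morphemes.complemented:
        raise MotifStateError("overlap generation expects un-complemented input sets")
    if min_overlap < 1:
        raise MotifError("min_overlap must be >= 1")
    derivations: dict[str, list[str]] = {}
    for zm in zfbs:
        z = zm.word
        for mm in morphemes:
            m = mm.word
            # offset of m's first base relative to z's first base
            for offset in range(-(len(m)) + min_overlap, len(z) - min_overlap + 1):
                ov = min(len(z), offset + len(m)) - max(0, offset)
                if ov < min_overlap:
                    continue
                merged = _merge_at_offset(z, m, offset)
                if merged is None:
                    continue
                if cpg_count(merged) < 2:
                    continue
                derivations.setdefault(merged, []).append(f"{zm.id},{mm.id},{offset:+d}")
    motifs = tuple(
        Motif(id="|".join(props), word=word, origin="overlap")
        for word, props in sorted(derivations.items())
    )
    return MotifSet(motifs=motifs, complemented=False)


@dataclass(frozen=True)
class OverlapReport:
    """Per-motif CpG audit of an overlap set."""

    rows: tuple[tuple[str, str, int, bool], ...]  # (id, word, cpg_count, flagged)
    min_cpg: int | None

    @property
    def flagged(self) -> tuple[str, ...]:
        return tuple(r[1] for r in self.rows if r[3])

    @property
    def passed(self) -> bool:
        return not self.flagged


def validate_overlap_set(ms: MotifSet | Iterable[Motif]) -> OverlapReport:
    """Audit CpG content: flag any overlap-origin motif with fewer than 2 CpGs."""
    motifs = list(ms)
    rows = []
    counts = []
    for m in motifs:
        c = cpg_count(m.word)
        counts.append(c)
        rows.append((m.id, m.word, c, m.origin == "overlap" and c < 2))
    return OverlapReport(rows=tuple(rows), min_cpg=min(counts) if counts else None)


_DATA_DIR = Path(__file__).parent / "data"

ZFBS_WORD = "TGCCGC"


def packaged_zfbs_set() -> MotifSet:
    """The ZFP57 binding-site hexamer as a one-word set (un-complemented)."""
    return MotifSet(motifs=(Motif(id="ZFBS", word=ZFBS_WORD, origin="zfbs"),))


def packaged_morpheme_set() -> MotifSet:
    """The packaged CpG-rich morpheme word list (editable data file)."""
    return with_origin(load_motif_file(_DATA_DIR / "morphemes_synthetic.txt"), "morpheme")


def packaged_overlap_set() -> MotifSet:
    """The packaged ZFBS-morph overlap word list.

    Loaded from an editable data file, not hard-coded, so users can replace
    it with any published composite-element list.  The shipped file is a
    synthetic stand-in generated by :func:`generate_overlap_motifs` from the
    hexamer and the packaged morpheme set; see the file header.
    """
    return with_origin(load_motif_file(_DATA_DIR / "overlaps_synthetic.txt"), "overlap")
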