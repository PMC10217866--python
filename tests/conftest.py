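"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each result by exhaustive enumeration,
independent of the implementation paths they check.
"""

from __future__ import annotations

import random

import pytest

from icrscan.genome_io import ChromosomeSequence
from icrscan.motifs import Motif, MotifSet
from icrscan.scan import MotifHit

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def naive_scan(seq: str, words: dict[str, tuple[str, str]]) -> list[tuple[int, int, str, str]]:
    """Check every offset of every word: (start, end, strand, motif_id) rows.

    *words* maps word -> (motif_id, strand).
    """
    out = []
    for word, (mid, strand) in words.items():
        k = len(word)
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] == word:
                out.append((i, i + k, strand, mid))
    return sorted(out, key=lambda r: (r[0], r[1], r[3]))


def brute_clusters(starts: list[int], window: int) -> list[list[int]]:
    """Connected components of the 'within window bases' graph on hit starts."""
    starts = sorted(starts)
    n = len(starts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(starts[j] - starts[i]) <= window:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(starts[i])
    return sorted(comps.values(), key=lambda c: c[0])


def brute_merge_words(z: str, m: str, min_overlap: int) -> set[str]:
    """All shortest superstrings of z and m with >= min_overlap overlapping,
    letter-compatible placements, by exhaustive construction of candidate
    superstrings (independent of the offset-walk in the implementation)."""
    out: set[str] = set()
    max_len = len(z) + len(m) - min_overlap
    for lenw in range(max(len(z), len(m)), max_len + 1):
        for pz in range(lenw - len(z) + 1):
            for pm in range(lenw - len(m) + 1):
                ov = min(pz + len(z), pm + len(m)) - max(pz, pm)
                if ov < min_overlap:
                    continue
                # positions must jointly cover all of w with no flanking slack
                if min(pz, pm) != 0 or max(pz + len(z), pm + len(m)) != lenw:
                    continue
                w = [""] * lenw
                ok = True
                for i, c in enumerate(z):
                    w[pz + i] = c
                for i, c in enumerate(m):
                    if w[pm + i] and w[pm + i] != c:
                        ok = False
                        break
                    w[pm + i] = c
                if ok and all(w):
                    out.add("".join(w))
    return out


def count_cg(word: str) -> int:
    return sum(1 for i in range(len(word) - 1) if word[i : i + 2] == "CG")


def make_hits(starts: list[int], chrom: str = "chrT", k: int = 6) -> list[MotifHit]:
    return [MotifHit(chrom, s, s + k, "+", "m") for s in sorted(starts)]


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260928)


@pytest.fixture
def toy_zfbs() -> MotifSet:
    return MotifSet(motifs=(Motif(id="ZFBS", word="TGCCGC", origin="zfbs"),))


@pytest.fixture
def toy_morphemes() -> MotifSet:
    return MotifSet(motifs=(Motif(id="M1", word="CGCGCG", origin="morpheme"),))


@pytest.fixture
def chrom_factory():
    def make(seq: str, name: str = "chrT") -> ChromosomeSequence:
        return ChromosomeSequence(name=name, residues=seq)

    return make
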