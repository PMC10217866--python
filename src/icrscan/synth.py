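"""Synthetic chromosomes with planted motif clusters and exact ground truth.

Every stage of the pipeline is testable without downloading an assembly:
this module emits a FASTA chromosome of i.i.d. background at a chosen GC
fraction, with copies of a motif planted in clusters (candidate-ICR-like),
as isolated sites (the background noise the density step must discard), and
nowhere else — chance occurrences of the motif or its reverse complement in
the background are resampled away ("scrubbing"), so the ground truth is
exact rather than probabilistic and a seeded run is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .density import DEFAULT_WINDOW, Peak
from .genome_io import ChromosomeSequence
from .motifs import Motif, MotifSet, expand_with_complements
from .scan import find_occurrences

__all__ = ["SyntheticTruth", "RecoveryReport", "simulate_genome", "truth_compare", "write_truth_bed"]

_BASES = np.array(list("ACGT"))


class PackingError(ValueError):
    """The requested planted elements cannot fit with the required separations."""


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth paired with a generated chromosome.

    ``planted_clusters`` rows are (chrom, start, n_motifs, span);
    ``isolated_sites`` rows are (chrom, start).  ``motif_positions`` lists
    the start of every planted word copy, cluster members and isolated sites
    alike.
    """

    planted_clusters: tuple[tuple[str, int, int, int], ...]
    isolated_sites: tuple[tuple[str, int], ...]
    motif_positions: tuple[int, ...]
    seed: int
    background: tuple[int, float]  # (length, GC fraction)


@dataclass(frozen=True)
class RecoveryReport:
    """How well called peaks recovered the planted truth."""

    recovered: int
    missed: int
    false_peaks: int
    isolated_suppressed: bool

    @property
    def planted(self) -> int:
        return self.recovered + self.missed

    @property
    def recovery_pct(self) -> float:
        return 100.0 * self.recovered / self.planted if self.planted else 100.0


def _sample_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=n, p=p)


def _cluster_offsets(n: int, span: int, k: int) -> list[int]:
    """Evenly spread n non-overlapping word starts across [0, span - k]."""
    if n == 1:
        return [0]
    stride = (span - k) // (n - 1)
    if stride < k:
        raise PackingError(
            f"cannot fit {n} non-overlapping {k}-mers in a span of {span} bases"
        )
    return [i * stride for i in range(n)]


def simulate_genome(
    length: int,
    gc: float,
    clusters_spec: Sequence[tuple[int, int] | int],
    isolated_spec: int,
    motif: Motif,
    window: int = DEFAULT_WINDOW,
    seed: int = 0,
    chrom_name: str = "chrS",
    min_separation: int = 5001,
    max_scrub_passes: int = 100,
) -> tuple[ChromosomeSequence, SyntheticTruth]:
    """Generate one chromosome with planted clusters and isolated sites.

    Parameters
    ----------
    clusters_spec :
        One entry per cluster: ``(n_motifs, span)`` or just ``n_motifs``
        (span then defaults to *window*).  ``n_motifs`` must be >= 2 and
        ``span`` <= *window*, so each planted cluster is guaranteed to fall
        within one scan window.
    isolated_spec :
        Number of isolated single-copy sites to plant.
    min_separation :
        Minimum background gap between the hulls of any two planted
        elements; must exceed *window* so that distinct elements can never
        chain into one peak.  The default (5001) leaves > 5 kb of scrubbed
        background between elements.

    Background bases are i.i.d. with the requested GC fraction, then every
    chance occurrence of the motif word or its reverse complement outside
    the planted intervals is resampled away, so scanning the result yields
    exactly the planted occurrences.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    if min_separation <= window:
        raise PackingError("min_separation must exceed the scan window")
    rng = np.random.default_rng(seed)
    k = len(motif.word)

    specs: list[tuple[int, int]] = []
    for entry in clusters_spec:
        n, span = entry if isinstance(entry, tuple) else (entry, window)
        if n < 2:
            raise PackingError("clusters need n_motifs >= 2; use isolated_spec for singles")
        if span > window:
            raise PackingError(f"cluster span {span} exceeds the scan window {window}")
        specs.append((n, span))

    # elements in random order so clusters and isolated sites interleave
    elements: list[tuple[str, int, int]] = [("cluster", n, span) for n, span in specs]
    elements += [("isolated", 1, k)] * isolated_spec
    n_elem = len(elements)
    if n_elem:
        elements = [elements[i] for i in rng.permutation(n_elem)]

    extents = [span for _, _, span in elements]
    slack = length - sum(extents) - (n_elem + 1) * min_separation
    if n_elem and slack < 0:
        raise PackingError(
            f"cannot place {n_elem} elements with {min_separation} b separation "
            f"in {length} bases (short by {-slack})"
        )
    placed: list[tuple[str, int, int, int]] = []  # (kind, start, n, span)
    if n_elem:
        extra = np.sort(rng.integers(0, slack + 1, size=n_elem))
        cursor = 0
        for i, (kind, n, span) in enumerate(elements):
            start = min_separation * (i + 1) + cursor + int(extra[i])
            placed.append((kind, start, n, span))
            cursor += span

    motif_positions: list[int] = []
    clusters: list[tuple[str, int, int, int]] = []
    isolated: list[tuple[str, int]] = []
    for kind, start, n, span in placed:
        if kind == "cluster":
            clusters.append((chrom_name, start, n, span))
            motif_positions.extend(start + off for off in _cluster_offsets(n, span, k))
        else:
            isolated.append((chrom_name, start))
            motif_positions.append(start)
    motif_positions.sort()

    codes = _sample_background(rng, length, gc)
    seq = _scrub(codes, motif, motif_positions, rng, gc, max_scrub_passes, chrom_name)
    truth = SyntheticTruth(
        planted_clusters=tuple(sorted(clusters, key=lambda c: c[1])),
        isolated_sites=tuple(sorted(isolated, key=lambda s: s[1])),
        motif_positions=tuple(motif_positions),
        seed=seed,
        background=(length, gc),
    )
    return seq, truth


def _scrub(
    codes: np.ndarray,
    motif: Motif,
    motif_positions: list[int],
    rng: np.random.Generator,
    gc: float,
    max_passes: int,
    chrom_name: str,
) -> ChromosomeSequence:
    """Stamp planted words and resample away every spurious occurrence."""
    k = len(motif.word)
    word_codes = np.array(["ACGT".index(c) for c in motif.word])
    planted_intervals = {(p, p + k) for p in motif_positions}
    in_planted = np.zeros(len(codes), dtype=bool)
    for p in motif_positions:
        in_planted[p : p + k] = True

    scan_set = expand_with_complements(MotifSet(motifs=(motif,)))
    for _ in range(max_passes):
        for p in motif_positions:
            codes[p : p + k] = word_codes
        seq = "".join(_BASES[codes])
        chrom = ChromosomeSequence(name=chrom_name, residues=seq)
        spurious = [
            h for h in find_occurrences(chrom, scan_set)
            if (h.start, h.end) not in planted_intervals
        ]
        if not spurious:
            return chrom
        for h in spurious:
            resample = [i for i in range(h.start, h.end) if not in_planted[i]]
            if not resample:
                break  # occurrence entirely inside planted DNA: unremovable
            idx = np.array(resample)
            codes[idx] = _sample_background(rng, len(idx), gc)
    raise PackingError("scrubbing did not converge; spurious motif occurrences remain")


def truth_compare(
    peaks: Sequence[Peak], truth: SyntheticTruth, window: int = DEFAULT_WINDOW
) -> RecoveryReport:
    """Score called peaks against the planted truth.

    A planted cluster is recovered when some peak's hull intersects the
    cluster span and that peak's count equals the planted copy number.
    Peaks matching no planted cluster are false peaks.  The report also
    records whether every isolated site was suppressed (no peak touches it).
    """
    matched_peaks: set[int] = set()
    recovered = 0
    for chrom, start, n, span in truth.planted_clusters:
        hit = False
        for i, p in enumerate(peaks):
            if p.chrom == chrom and p.start < start + span and p.end > start and p.count == n:
                hit = True
                matched_peaks.add(i)
                break
        recovered += hit
    false_peaks = len(peaks) - len(matched_peaks)
    isolated_ok = True
    for chrom, start in truth.isolated_sites:
        for p in peaks:
            if p.chrom == chrom and p.start <= start < p.end:
                isolated_ok = False
    return RecoveryReport(
        recovered=recovered,
        missed=len(truth.planted_clusters) - recovered,
        false_peaks=false_peaks,
        isolated_suppressed=isolated_ok,
    )


def write_truth_bed(truth: SyntheticTruth, path: str | Path, motif_len: int) -> Path:
    """Write the planted truth as BED: one line per planted element."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write('track name="planted_truth" description="synthetic planted elements"\n')
        rows = [
            (c, s, s + span, f"cluster:{n}") for c, s, n, span in truth.planted_clusters
        ] + [(c, s, s + motif_len, "isolated:1") for c, s in truth.isolated_sites]
        for chrom, start, end, name in sorted(rows, key=lambda r: r[1]):
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
    return path
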