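"""Sliding-window density of composite-element hits, and peak calling.

The core of the method: count ZFBS-morph overlap occurrences in a sliding
window of 850 bases, discard isolated occurrences (a lone composite element
is background noise — real imprinting control regions carry clusters), and
call the surviving clusters as peaks.  Peak intensity is the number of
elements encompassed: peaks covering three or more are robust candidate
ICRs; peaks covering exactly two may be true or false positives and are
classified "weak".

Peak calling is implemented by chaining: consecutive hits whose starts lie
within one window length of each other belong to the same cluster.  With a
step-1 sliding window this is equivalent (up to a one-base boundary case
documented in the methods note) to suppressing count-1 windows in the
density track, and it gives each peak a literal extent — the hull of its
member hits — so "a peak encompasses k overlaps" is true of the reported
interval.
"""

from __future__ import annotations

import bisect
import statistics
from dataclasses import dataclass

import pandas as pd

from .scan import MotifHit

__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_ROBUST_MIN",
    "DensityTrack",
    "Peak",
    "window_counts",
    "call_peaks",
    "summarize_peaks",
]

#: Sliding-window length in bases used for the density plots.
DEFAULT_WINDOW = 850

#: Minimum number of composite elements for a robust peak.
DEFAULT_ROBUST_MIN = 3

#: Default step for the exported wiggle (window/10); peak logic uses the
#: step-1-equivalent chaining formulation regardless.
DEFAULT_WIG_STEP = DEFAULT_WINDOW // 10


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DensityTrack:
    """Per-window hit counts after isolated-occurrence suppression.

    ``values`` holds (window_start, count) pairs; window starts are multiples
    of ``step``, strictly increasing; no count of exactly 1 survives.
    """

    chrom: str
    window: int
    step: int
    values: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev = -1
        for w, c in self.values:
            if c < 0 or c == 1:
                raise ValueError(f"invalid suppressed count {c} at window {w}")
            if w % self.step != 0 or w <= prev:
                raise ValueError(f"window starts must be increasing multiples of step (got {w})")
            prev = w


@dataclass(frozen=True)
class Peak:
    """A maximal cluster of composite-element hits: a candidate ICR.

    ``start``/``end`` span the hull of the member hits; ``count`` is the
    number of members; ``klass`` is "robust" (count >= robust_min) or "weak".
    """

    chrom: str
    start: int
    end: int
    count: int
    klass: str
    member_hits: tuple[MotifHit, ...]

    def __post_init__(self) -> None:
        if self.count < 2:
            raise ValueError("a peak requires at least 2 member hits")
        if self.klass not in ("robust", "weak"):
            raise ValueError(f"invalid peak class {self.klass!r}")


def window_counts(
    hits: list[MotifHit],
    chrom_length: int,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_WIG_STEP,
    chrom: str | None = None,
) -> DensityTrack:
    """Count hit starts per window [w, w+window), suppressing counts of 1.

    Windows are placed at 0, step, 2*step, ... covering the chromosome
    (the trailing partial window is included).  A count of exactly 1 is an
    isolated occurrence within that window and is set to 0.

    *hits* must be sorted and deduped; *step* must not exceed *window*
    (a larger step would leave gaps that drop hits from every window).
    """
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    if not 1 <= step <= window:
        raise ConfigurationError(f"step must satisfy 1 <= step <= window (got step={step})")
    name = chrom if chrom is not None else (hits[0].chrom if hits else "chr")
    starts = [h.start for h in hits]
    values: list[tuple[int, int]] = []
    w = 0
    while w < chrom_length:
        lo = bisect.bisect_left(starts, w)
        hi = bisect.bisect_left(starts, w + window)
        count = hi - lo
        if count == 1:
            count = 0
        values.append((w, count))
        w += step
    return DensityTrack(chrom=name, window=window, step=step, values=tuple(values))


def call_peaks(
    hits: list[MotifHit],
    window: int = DEFAULT_WINDOW,
    robust_min: int = DEFAULT_ROBUST_MIN,
) -> list[Peak]:
    """Chain sorted, deduped hits into maximal clusters and call peaks.

    Consecutive hits whose starts differ by at most *window* join the same
    cluster.  Singleton clusters are the isolated occurrences the method
    disregards.  Surviving clusters become peaks spanning the hull of their
    members, classified robust (count >= *robust_min*) or weak.
    """
    if robust_min < 2:
        raise ConfigurationError("robust_min must be >= 2")
    peaks: list[Peak] = []
    cluster: list[MotifHit] = []

    def flush() -> None:
        if len(cluster) >= 2:
            peaks.append(
                Peak(
                    chrom=cluster[0].chrom,
                    start=min(h.start for h in cluster),
                    end=max(h.end for h in cluster),
                    count=len(cluster),
                    klass="robust" if len(cluster) >= robust_min else "weak",
                    member_hits=tuple(cluster),
                )
            )

    for h in hits:
        if cluster and (h.chrom != cluster[-1].chrom or h.start - cluster[-1].start > window):
            flush()
            cluster = []
        cluster.append(h)
    flush()
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def summarize_peaks(peaks: list[Peak]) -> pd.DataFrame:
    """Per-chromosome peak summary table.

    Columns: chrom, total, robust, weak, max_count, median_width.
    Empty input yields an empty table with those columns.
    """
    cols = ["chrom", "total", "robust", "weak", "max_count", "median_width"]
    if not peaks:
        return pd.DataFrame(columns=cols)
    rows = []
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        ps = by_chrom[chrom]
        robust = sum(1 for p in ps if p.klass == "robust")
        rows.append(
            {
                "chrom": chrom,
                "total": len(ps),
                "robust": robust,
                "weak": len(ps) - robust,
                "max_count": max(p.count for p in ps),
                "median_width": statistics.median(p.end - p.start for p in ps),
            }
        )
    return pd.DataFrame(rows, columns=cols)
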