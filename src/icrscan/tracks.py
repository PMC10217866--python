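"""UCSC custom-track output and gene-proximity annotation.

Three custom tracks reproduce the browser upload the method was built for:
a BED of hexamer (TGCCGC) positions, a BED of ZFBS-morph overlap positions,
and a fixedStep wiggle of the suppressed density.  A peak BED is written
alongside as derived output.  BED is 0-based half-open, wiggle 1-based (UCSC
conventions); the conversion lives only here, in the writers, and is
round-trip tested.

Gene annotation replaces the manual browsing step: genes near a peak are
candidate imprinted genes, reported with signed hull-to-hull distances
(0 for overlap, negative when the gene ends before the peak starts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from intervaltree import IntervalTree

from .density import DensityTrack, Peak
from .scan import MotifHit

__all__ = [
    "GeneFeature",
    "AnnotatedPeak",
    "write_hit_bed",
    "write_density_wig",
    "write_peak_bed",
    "bundle_tracks",
    "annotate_peaks",
    "read_genes_bed",
    "read_genes_gff3",
    "read_bed_hits",
    "read_wig",
]

DEFAULT_RADIUS = 10_000


class TrackInputError(ValueError):
    pass


@dataclass(frozen=True)
class GeneFeature:
    """A gene model interval (consumed for annotation, never computed)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_name: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_name!r}: start must be < end")
        if not self.gene_name:
            raise ValueError("gene name must be non-empty")


@dataclass(frozen=True)
class AnnotatedPeak:
    """A peak plus the genes within the annotation radius, nearest first."""

    peak: Peak
    genes: tuple[tuple[str, int], ...]  # (gene_name, signed distance; 0 = overlap)


def _track_header(name: str, description: str, track_type: str | None = None) -> str:
    type_part = f"type={track_type} " if track_type else ""
    return f'track {type_part}name="{name}" description="{description}"\n'


def write_hit_bed(
    hits: Sequence[MotifHit], track_name: str, out: str | Path, description: str | None = None
) -> Path:
    """Write sorted hits as BED6 with a UCSC ``track`` header line."""
    out = Path(out)
    with out.open("w") as fh:
        fh.write(_track_header(track_name, description or track_name))
        for h in hits:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.motif_id}\t0\t{h.strand}\n")
    return out


def write_density_wig(
    track: DensityTrack,
    out: str | Path,
    track_name: str = "overlap_density",
    suppress_zeros: bool = True,
) -> Path:
    """Write a density track as fixedStep wiggle (1-based starts, span=step).

    Zero runs are skipped when *suppress_zeros* is set, splitting the output
    into multiple fixedStep blocks; the browser treats absent positions as
    empty, which matches the meaning of a suppressed count.
    """
    out = Path(out)
    with out.open("w") as fh:
        fh.write(_track_header(track_name, "ZFBS-morph overlap density", "wiggle_0"))
        in_block = False
        for w, c in track.values:
            if suppress_zeros and c == 0:
                in_block = False
                continue
            if not in_block:
                fh.write(
                    f"fixedStep chrom={track.chrom} start={w + 1} "
                    f"step={track.step} span={track.step}\n"
                )
                in_block = True
            fh.write(f"{c}\n")
    return out


def write_peak_bed(peaks: Sequence[Peak], out: str | Path) -> Path:
    """Write peaks as BED5: name ``robust:count``/``weak:count``, score = count."""
    for a, b in zip(peaks, peaks[1:]):
        if (a.chrom, a.start) > (b.chrom, b.start):
            raise TrackInputError("peaks must be sorted by (chrom, start)")
    out = Path(out)
    with out.open("w") as fh:
        fh.write(_track_header("candidate_ICRs", "density peaks (candidate ICRs)"))
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.klass}:{p.count}\t{p.count}\n")
    return out


def bundle_tracks(
    hits_zfbs: Sequence[MotifHit] | None,
    hits_overlap: Sequence[MotifHit] | None,
    density: DensityTrack | Sequence[DensityTrack] | None,
    out_dir: str | Path,
    peaks: Sequence[Peak] | None = None,
) -> Path:
    """Write the three browser custom tracks plus a manifest.

    The three tracks are: hexamer-hit BED, overlap-hit BED, density wiggle.
    When *peaks* is given a peak BED is written alongside, listed in the
    manifest as derived output rather than a fourth track.
    """
    for label, value in (
        ("zfbs hits", hits_zfbs),
        ("overlap hits", hits_overlap),
        ("density track", density),
    ):
        if value is None:
            raise TrackInputError(f"bundle_tracks: missing {label}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    zfbs_path = write_hit_bed(hits_zfbs, "TGCCGC_sites", out_dir / "zfbs_hits.bed",
                              "ZFP57 binding-site hexamer positions")
    ov_path = write_hit_bed(hits_overlap, "ZFBS_morph_overlaps", out_dir / "overlap_hits.bed",
                            "ZFBS-morph overlap positions")
    densities = [density] if isinstance(density, DensityTrack) else list(density)
    wig_path = out_dir / "overlap_density.wig"
    with wig_path.open("w") as fh:
        fh.write(_track_header("overlap_density", "ZFBS-morph overlap density", "wiggle_0"))
    for d in densities:
        tmp = write_density_wig(d, out_dir / f".{d.chrom}.wig.part")
        with tmp.open() as part, wig_path.open("a") as fh:
            next(part)  # drop the per-chromosome track header
            fh.write(part.read())
        tmp.unlink()
    manifest = out_dir / "manifest.txt"
    with manifest.open("w") as fh:
        fh.write(f"track_zfbs_bed\t{zfbs_path.name}\n")
        fh.write(f"track_overlap_bed\t{ov_path.name}\n")
        fh.write(f"track_density_wig\t{wig_path.name}\n")
        if peaks is not None:
            peak_path = write_peak_bed(peaks, out_dir / "peaks.bed")
            fh.write(f"derived_peak_bed\t{peak_path.name}\n")
    return manifest


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneFeature],
    radius: int = DEFAULT_RADIUS,
) -> list[AnnotatedPeak]:
    """Attach every gene within *radius* bases of each peak hull.

    Distances are hull-to-hull: 0 when the intervals overlap, negative when
    the gene ends before the peak starts, positive when it starts after the
    peak ends.  Genes are listed nearest first.  A peak on a chromosome with
    no gene models gets an empty annotation.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    out: list[AnnotatedPeak] = []
    for p in peaks:
        tree = trees.get(p.chrom)
        found: list[tuple[str, int]] = []
        if tree is not None:
            for iv in tree.overlap(p.start - radius, p.end + radius):
                g: GeneFeature = iv.data
                if g.end <= p.start:
                    dist = -(p.start - g.end)
                elif g.start >= p.end:
                    dist = g.start - p.end
                else:
                    dist = 0
                if abs(dist) <= radius:
                    found.append((g.gene_name, dist))
        found.sort(key=lambda t: (abs(t[1]), t[0]))
        out.append(AnnotatedPeak(peak=p, genes=tuple(found)))
    return out


# ---------------------------------------------------------------------------
# readers (round-trip partners and gene-model ingestion)


def read_bed_hits(path: str | Path) -> list[MotifHit]:
    """Parse a hit BED written by :func:`write_hit_bed` back into hits."""
    hits: list[MotifHit] = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith(("track", "browser", "#")) or not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            hits.append(MotifHit(chrom, int(start), int(end), strand, name))
    return hits


def read_wig(path: str | Path) -> list[tuple[str, int, int, int]]:
    """Parse a fixedStep wiggle into (chrom, 0-based start, step, value) rows."""
    rows: list[tuple[str, int, int, int]] = []
    chrom, pos, step = None, 0, 1
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1
                step = int(fields.get("step", 1))
                continue
            if chrom is None:
                raise TrackInputError("wiggle value before any fixedStep declaration")
            rows.append((chrom, pos, step, int(float(line))))
            pos += step
    return rows


def read_genes_bed(path: str | Path) -> list[GeneFeature]:
    """Gene models from BED (>= 4 columns; strand from column 6 if present)."""
    genes: list[GeneFeature] = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith(("track", "browser", "#")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise TrackInputError(f"BED gene line needs >= 4 columns: {line!r}")
            strand = f[5] if len(f) >= 6 and f[5] in "+-" else "+"
            genes.append(GeneFeature(f[0], int(f[1]), int(f[2]), strand, f[3]))
    return genes


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_genes_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneFeature]:
    """Gene models from GFF3, keeping *feature_type* rows.

    The gene name comes from the ``Name`` attribute, falling back to ``ID``.
    GFF3 coordinates are 1-based inclusive and are converted to 0-based
    half-open here.
    """
    genes: list[GeneFeature] = []
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise TrackInputError(f"GFF3 line needs 9 columns: {line!r}")
            if f[2] != feature_type:
                continue
            attrs = _gff3_attributes(f[8])
            name = attrs.get("Name") or attrs.get("ID")
            if not name:
                raise TrackInputError(f"GFF3 gene without Name/ID attribute: {line!r}")
            strand = f[6] if f[6] in "+-" else "+"
            genes.append(GeneFeature(f[0], int(f[3]) - 1, int(f[4]), strand, name))
    return genes
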