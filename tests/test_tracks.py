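"""UCSC track writers (round-trip tested) and gene-proximity annotation."""

import pytest

from icrscan.density import DensityTrack, call_peaks, window_counts
from icrscan.scan import MotifHit
from icrscan.tracks import (
    GeneFeature,
    TrackInputError,
    annotate_peaks,
    bundle_tracks,
    read_bed_hits,
    read_genes_bed,
    read_genes_gff3,
    read_wig,
    write_density_wig,
    write_hit_bed,
    write_peak_bed,
)

from .conftest import make_hits


def peak(start, end, count, chrom="chrT"):
    (p,) = call_peaks(make_hits(list(range(start, start + count * 10, 10)), chrom=chrom), 850)
    assert p.count == count
    return p


class TestHitBed:
    def test_bed6_line_format(self, tmp_path):
        out = write_hit_bed([MotifHit("chr9", 100, 106, "+", "TGCCGC")], "t", tmp_path / "h.bed")
        lines = out.read_text().splitlines()
        assert lines[0].startswith("track ")
        assert lines[1] == "chr9\t100\t106\tTGCCGC\t0\t+"

    def test_empty_hits_header_only(self, tmp_path):
        out = write_hit_bed([], "t", tmp_path / "h.bed")
        assert len(out.read_text().splitlines()) == 1

    def test_line_count_is_hits_plus_header(self, tmp_path):
        hits = make_hits([0, 10, 20, 30])
        out = write_hit_bed(hits, "t", tmp_path / "h.bed")
        assert len(out.read_text().splitlines()) == len(hits) + 1

    def test_round_trip_exact(self, tmp_path):
        hits = [
            MotifHit("chr1", 5, 11, "+", "a"),
            MotifHit("chr1", 7, 16, "-", "b"),
            MotifHit("chr2", 0, 6, "-", "c"),
        ]
        out = write_hit_bed(hits, "t", tmp_path / "h.bed")
        assert read_bed_hits(out) == hits


class TestDensityWig:
    def test_one_based_conversion(self, tmp_path):
        track = DensityTrack(chrom="chrT", window=850, step=850, values=((0, 3),))
        text = write_density_wig(track, tmp_path / "d.wig").read_text()
        assert "fixedStep chrom=chrT start=1 step=850 span=850" in text
        assert text.splitlines()[-1] == "3"

    def test_all_zero_track_suppressed_to_no_blocks(self, tmp_path):
        track = DensityTrack(chrom="chrT", window=850, step=85, values=((0, 0), (85, 0)))
        text = write_density_wig(track, tmp_path / "d.wig").read_text()
        assert "fixedStep" not in text

    def test_values_round_trip_through_parser(self, tmp_path):
        hits = make_hits([100, 200, 300, 5000, 9000, 9100])
        track = window_counts(hits, 12_000, window=850, step=85)
        out = write_density_wig(track, tmp_path / "d.wig")
        parsed = {(c, s): v for c, s, _, v in read_wig(out)}
        for w, v in track.values:
            if v > 0:
                assert parsed[("chrT", w)] == v
        assert all(v > 0 for v in parsed.values())


class TestPeakBed:
    def test_robust_and_weak_naming(self, tmp_path):
        peaks = [peak(0, None, 3), peak(5000, None, 2)]
        lines = write_peak_bed(peaks, tmp_path / "p.bed").read_text().splitlines()
        assert lines[1].split("\t")[3:] == ["robust:3", "3"]
        assert lines[2].split("\t")[3:] == ["weak:2", "2"]

    def test_unsorted_peaks_rejected(self, tmp_path):
        peaks = [peak(5000, None, 2), peak(0, None, 3)]
        with pytest.raises(TrackInputError):
            write_peak_bed(peaks, tmp_path / "p.bed")


class TestBundle:
    def test_manifest_lists_exactly_three_tracks(self, tmp_path):
        track = window_counts(make_hits([0, 100]), 2000, 850, 850)
        manifest = bundle_tracks(make_hits([0]), make_hits([0, 100]), track, tmp_path / "out")
        rows = [l.split("\t") for l in manifest.read_text().splitlines()]
        track_rows = [r for r in rows if r[0].startswith("track_")]
        assert len(track_rows) == 3
        for _, fname in rows:
            assert (tmp_path / "out" / fname).exists()

    def test_missing_component_names_it(self, tmp_path):
        with pytest.raises(TrackInputError, match="overlap hits"):
            bundle_tracks(make_hits([0]), None, None, tmp_path / "out")

    def test_peaks_are_derived_output_not_a_fourth_track(self, tmp_path):
        hits = make_hits([0, 100, 200])
        track = window_counts(hits, 2000, 850, 850)
        manifest = bundle_tracks(hits, hits, track, tmp_path / "out",
                                 peaks=call_peaks(hits, 850))
        rows = dict(l.split("\t") for l in manifest.read_text().splitlines())
        assert sum(1 for k in rows if k.startswith("track_")) == 3
        assert "derived_peak_bed" in rows


class TestAnnotatePeaks:
    def test_overlapping_gene_distance_zero(self):
        p = peak(1000, None, 3)
        genes = [GeneFeature("chrT", 1010, 5000, "+", "GENE1")]
        (ap,) = annotate_peaks([p], genes, radius=10_000)
        assert ap.genes == (("GENE1", 0),)

    def test_downstream_gene_positive_gap(self):
        p = peak(1000, None, 2)  # hull [1000, 1016)
        genes = [GeneFeature("chrT", 2000, 3000, "+", "G")]
        (ap,) = annotate_peaks([p], genes, radius=10_000)
        assert ap.genes == (("G", 2000 - p.end),)

    def test_upstream_gene_negative_distance(self):
        p = peak(5000, None, 2)
        genes = [GeneFeature("chrT", 100, 400, "+", "G")]
        (ap,) = annotate_peaks([p], genes, radius=10_000)
        assert ap.genes[0][1] == -(5000 - 400)

    def test_radius_zero_excludes_disjoint_gene(self):
        p = peak(1000, None, 2)
        genes = [GeneFeature("chrT", 2000, 3000, "+", "G")]
        (ap,) = annotate_peaks([p], genes, radius=0)
        assert ap.genes == ()

    def test_unknown_chromosome_gives_empty_annotation(self):
        p = peak(1000, None, 2)
        (ap,) = annotate_peaks([p], [GeneFeature("chrZ", 0, 10, "+", "G")], radius=10_000)
        assert ap.genes == ()

    def test_agrees_with_brute_force_join(self, rng):
        for _ in range(25):
            peaks = [peak(s, None, 2) for s in sorted(rng.sample(range(0, 200_000, 100), 5))]
            genes = [
                GeneFeature("chrT", g, g + rng.randint(50, 4000), "+", f"G{i}")
                for i, g in enumerate(rng.sample(range(0, 220_000, 37), 30))
            ]
            radius = rng.choice([0, 500, 10_000])
            annotated = annotate_peaks(peaks, genes, radius)
            for ap in annotated:
                p = ap.peak
                expected = {}
                for g in genes:
                    if g.end <= p.start:
                        d = -(p.start - g.end)
                    elif g.start >= p.end:
                        d = g.start - p.end
                    else:
                        d = 0
                    if abs(d) <= radius:
                        expected[g.gene_name] = d
                assert dict(ap.genes) == expected


class TestGeneReaders:
    def test_bed_genes(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t200\tGENE1\t0\t-\nchr1\t300\t400\tGENE2\n")
        genes = read_genes_bed(p)
        assert genes[0] == GeneFeature("chr1", 100, 200, "-", "GENE1")
        assert genes[1].strand == "+"

    def test_gff3_genes_name_preferred_over_id(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1;Name=PLAGL1\n"
            "chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\tgene\t301\t400\t.\t-\t.\tID=g2\n"
        )
        genes = read_genes_gff3(p)
        assert genes[0] == GeneFeature("chr1", 100, 200, "+", "PLAGL1")
        assert genes[1].gene_name == "g2" and genes[1].start == 300
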