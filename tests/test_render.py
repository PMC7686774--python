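"""Figure layout, SVG generation, rasterization and bin reports."""

import io

import numpy as np
import pytest
from lxml import etree
from PIL import Image

from snpview import (
    Metric,
    TrackSpec,
    ViewSpec,
    bin_counts,
    bin_report,
    compare_pair,
    rasterize,
    render_svg,
    render_view,
    scale_histogram,
)
from snpview.binning import haplotype_presence
from snpview.model import BinSeries, ChromosomeSet
from snpview.render import (
    DRAW_HEIGHT,
    TRACK_WIDTH,
    layout_genome,
    load_bed,
)


def _spec(**kw):
    defaults = dict(tracks=[TrackSpec("R", "C")], bin_size=500_000)
    defaults.update(kw)
    return ViewSpec(**defaults)


def _series(counts, chrom="Chr1", chrom_length=None, bin_size=500_000):
    if chrom_length is None:
        chrom_length = len(counts) * bin_size
    return BinSeries(
        chrom=chrom, chrom_length=chrom_length, bin_size=bin_size,
        counts=np.array(counts), metric=Metric.DIFFERENT, pair=("R", "C"),
    )


class TestLayout:
    def test_uniform_scale_across_chromosomes(self):
        chroms = ChromosomeSet([("Chr1", 1_000_000), ("Chr2", 2_000_000)])
        layout = layout_genome(chroms, _spec())
        assert layout.px_per_bp * 2_000_000 == pytest.approx(DRAW_HEIGHT)
        # backbone pixel lengths are px_per_bp * length, so 2:1 exactly
        assert (2_000_000 * layout.px_per_bp) == pytest.approx(
            2 * (1_000_000 * layout.px_per_bp)
        )

    def test_ruler_tic_count_is_floor_length_over_interval(self):
        chroms = ChromosomeSet([("Chr1", 2_000_000)])
        layout = layout_genome(chroms, _spec(ruler_interval=500_000))
        assert layout.ruler_tics == [500_000, 1_000_000, 1_500_000, 2_000_000]

    def test_subpixel_bins_warn(self):
        chroms = ChromosomeSet([("Chr1", 100_000_000)])
        with pytest.warns(UserWarning, match="one pixel"):
            layout_genome(chroms, _spec(bin_size=1000, ruler_interval=10_000_000))

    def test_chromosome_filter_restricts_layout(self):
        chroms = ChromosomeSet([("Chr1", 1_000_000), ("Chr2", 1_000_000)])
        layout = layout_genome(chroms, _spec(chromosome_filter=["Chr2"]))
        assert list(layout.chrom_x) == ["Chr2"]

    def test_empty_filter_is_an_error(self):
        chroms = ChromosomeSet([("Chr1", 1_000_000)])
        with pytest.raises(ValueError):
            layout_genome(chroms, _spec(chromosome_filter=["ChrX"]))


class TestRenderSvg:
    def test_identical_inputs_give_identical_bytes(self, small_sim):
        ds, _ = small_sim
        spec = _spec(tracks=[TrackSpec("F1", "D1")], title="Run twice")
        assert render_view(ds, spec) == render_view(ds, spec)

    def test_all_zero_histogram_draws_no_bars(self):
        spec = _spec()
        scaled = scale_histogram([_series([0, 0, 0])])
        svg = render_svg([scaled], spec)
        root = etree.fromstring(svg.encode())
        track = root.find(".//{*}g[@id='track0_Chr1']")
        assert track is not None and len(track) == 0
        assert root.find(".//{*}g[@id='backbones']") is not None
        assert root.find(".//{*}g[@id='key']") is not None

    def test_sides_partition_bars_around_backbone(self):
        spec = ViewSpec(
            tracks=[
                TrackSpec("R", "C", side="left", color="#aa0000"),
                TrackSpec("R", "C", side="right", color="#00aa00"),
            ],
            bin_size=500_000,
        )
        scaled = scale_histogram([_series([2, 8, 4])])
        svg = render_svg([scaled, scaled], spec)
        root = etree.fromstring(svg.encode())
        layout = layout_genome(ChromosomeSet([("Chr1", 1_500_000)]), spec)
        backbone_x = layout.chrom_x["Chr1"]
        left = root.findall(".//{*}g[@id='track0_Chr1']/{*}rect")
        right = root.findall(".//{*}g[@id='track1_Chr1']/{*}rect")
        assert left and right
        for r in left:
            assert float(r.get("x")) + float(r.get("width")) < backbone_x
        for r in right:
            assert float(r.get("x")) > backbone_x

    def test_mixed_bin_sizes_rejected(self):
        spec = ViewSpec(tracks=[TrackSpec("R", "C"), TrackSpec("R", "C")])
        a = scale_histogram([_series([1, 2])])
        b = scale_histogram([_series([1, 2], bin_size=250_000)])
        with pytest.raises(ValueError, match="bin size"):
            render_svg([a, b], spec)

    def test_key_lists_each_comparison_with_its_color(self, small_sim):
        ds, _ = small_sim
        spec = ViewSpec(
            tracks=[
                TrackSpec("F1", "D1", color="#123456"),
                TrackSpec("F1", "F2", color="#654321", side="left"),
            ]
        )
        svg = render_view(ds, spec)
        assert "#123456" in svg and "#654321" in svg
        assert "D1 vs F1" in svg and "F2 vs F1" in svg

    def test_haplotype_cells_only_where_present(self):
        spec = _spec(tracks=[TrackSpec("R", "C", display="haplotype", threshold=5)])
        scaled = haplotype_presence([_series([0, 4, 5, 9])], 5)
        svg = render_svg([scaled], spec)
        root = etree.fromstring(svg.encode())
        cells = root.findall(".//{*}g[@id='track0_Chr1']/{*}rect")
        assert len(cells) == 2  # bins with counts 5 and 9 only

    def test_annotation_overlay_draws_on_backbone(self, small_sim, tmp_path):
        ds, _ = small_sim
        bed = tmp_path / "centromeres.bed"
        bed.write_text("Chr1\t3000000\t4000000\nChr2\t2000000\t2500000\n")
        spec = _spec(tracks=[TrackSpec("F1", "D1")])
        svg = render_view(ds, spec, annotations=load_bed(bed))
        root = etree.fromstring(svg.encode())
        ann = root.find(".//{*}g[@id='annotations']")
        assert ann is not None and len(ann) == 2


class TestSvgGeometryAudit:
    def test_histogram_bar_widths_recover_counts(self, noisy_sim):
        """Parse bar geometry back into counts (within 1 px of quantization)."""
        ds, _ = noisy_sim
        pc = compare_pair(ds, "F1", "D1")
        series = bin_counts(pc, Metric.DIFFERENT, 500_000, ds.chromosomes)
        spec = _spec(tracks=[TrackSpec("F1", "D1")])
        scaled = scale_histogram(series)
        svg = render_svg([scaled], spec)
        root = etree.fromstring(svg.encode())
        layout = layout_genome(ds.chromosomes, spec)
        m, M = scaled[0].scale_min, scaled[0].scale_max
        for s in series:
            rects = root.findall(f".//{{*}}g[@id='track0_{s.chrom}']/{{*}}rect")
            got = np.zeros(s.n_bins)
            bin_px = s.bin_size * layout.px_per_bp
            for r in rects:
                y = float(r.get("y"))
                k = int(round((y - layout.y0) / bin_px))
                got[k] = float(r.get("width")) / TRACK_WIDTH * (M - m) + m
            tol = (M - m) / TRACK_WIDTH  # one pixel of bar width
            assert np.all(np.abs(got - s.counts) <= tol + 1e-9)


class TestRasterize:
    def test_png_dimensions_match_viewbox(self):
        svg = (
            '<svg xmlns="http://www.w3.org/2000/svg" width="1000" height="500" '
            'viewBox="0 0 1000 500"><rect x="1" y="1" width="5" height="5" '
            'fill="#ff0000"/></svg>'
        )
        img = Image.open(io.BytesIO(rasterize(svg)))
        assert img.size == (1000, 500)
        img2 = Image.open(io.BytesIO(rasterize(svg, scale=2.0)))
        assert img2.size == (2000, 1000)

    def test_rendered_figure_rasterizes(self, small_sim):
        ds, _ = small_sim
        svg = render_view(ds, _spec(tracks=[TrackSpec("F1", "D1")], title="t"))
        img = Image.open(io.BytesIO(rasterize(svg)))
        assert img.size[0] > 100 and img.size[1] > 100
        # the red default track color must appear somewhere
        colors = {c for _, c in img.getcolors(maxcolors=1_000_000)}
        assert (204, 0, 0) in colors

    def test_invalid_svg_rejected(self):
        with pytest.raises(ValueError, match="invalid SVG"):
            rasterize("this is not xml <")
        with pytest.raises(ValueError, match="invalid SVG"):
            rasterize("<notsvg/>")


class TestBinReport:
    def test_coordinates_follow_bin_convention(self):
        series = [_series([1, 2, 3, 4], chrom_length=2_000_000)]
        report = bin_report(series, "Chr1", 2)
        assert (report.start, report.end) == (1_000_001, 1_500_000)

    def test_values_and_total_from_counts(self, noisy_sim):
        ds, _ = noisy_sim
        tracks, totals = [], []
        for comp in ("F2", "D1"):
            pc = compare_pair(ds, "F1", comp)
            tracks += bin_counts(pc, Metric.DIFFERENT, 500_000, ds.chromosomes)
            totals += bin_counts(pc, Metric.TOTAL, 500_000, ds.chromosomes)
        report = bin_report(tracks, "Chr1", 3, totals=totals)
        for s in tracks:
            if s.chrom == "Chr1":
                assert report.values[s.pair[1]] == int(s.counts[3])
        expected_total = sum(
            int(t.counts[3]) for t in totals if t.chrom == "Chr1"
        )
        assert report.total == expected_total

    def test_out_of_range_bin_reports_valid_range(self):
        series = [_series([1, 2])]
        with pytest.raises(IndexError, match="0..1"):
            bin_report(series, "Chr1", 5)


def test_view_requires_at_least_one_track():
    with pytest.raises(ValueError, match="track"):
        ViewSpec(tracks=[])


def test_display_specific_parameters_enforced():
    with pytest.raises(ValueError, match="threshold"):
        TrackSpec("R", "C", display="histogram", threshold=5)
    with pytest.raises(ValueError, match="min/max"):
        TrackSpec("R", "C", display="haplotype", user_max=10.0)
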