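"""Bin assignment, counting and the three display-type transformations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpview import (
    Metric,
    Verdict,
    bin_counts,
    compare_pair,
    haplotype_presence,
    scale_heatmap,
    scale_histogram,
)
from snpview.binning import assign_bin, interpolate_ramp
from snpview.model import (
    BinSeries,
    ChromosomeSet,
    PairComparison,
    SiteClassification,
)


@pytest.mark.parametrize(
    "pos, bin_size, expected",
    [
        (1, 500_000, 0),
        (500_000, 500_000, 0),  # inclusive upper boundary
        (500_001, 500_000, 1),
        (1_234_567, 500_000, 2),
        (1, 1, 0),
        (7, 3, 2),
    ],
)
def test_assign_bin(pos, bin_size, expected):
    assert assign_bin(pos, bin_size) == expected


def test_assign_bin_rejects_bad_positions():
    with pytest.raises(ValueError):
        assign_bin(0, 500_000)
    with pytest.raises(ValueError):
        assign_bin(10, 0)


def _pc(verdicts_at):
    """Build a PairComparison from (chrom, pos, verdict) triples."""
    return PairComparison(
        ref_sample="R",
        comp_sample="C",
        classifications=[
            SiteClassification(c, p, Verdict[v]) for c, p, v in verdicts_at
        ],
    )


class TestBinCounts:
    def test_hand_placed_sites(self):
        pc = _pc(
            [
                ("Chr1", 10, "DIFFERENT"),
                ("Chr1", 20, "DIFFERENT"),
                ("Chr1", 600_000, "DIFFERENT"),
            ]
        )
        chroms = ChromosomeSet([("Chr1", 1_000_000)])
        (series,) = bin_counts(pc, Metric.DIFFERENT, 500_000, chroms)
        assert series.counts.tolist() == [2, 1]

    def test_missing_never_counted_and_total_is_same_plus_different(self):
        pc = _pc(
            [
                ("Chr1", 5, "SAME"),
                ("Chr1", 15, "DIFFERENT"),
                ("Chr1", 25, "MISSING"),
            ]
        )
        chroms = ChromosomeSet([("Chr1", 100)])
        total = bin_counts(pc, Metric.TOTAL, 100, chroms)[0].counts
        same = bin_counts(pc, Metric.SAME, 100, chroms)[0].counts
        diff = bin_counts(pc, Metric.DIFFERENT, 100, chroms)[0].counts
        assert total.tolist() == [2]
        assert (same + diff == total).all()

    def test_chromosome_without_sites_gets_zero_series(self):
        pc = _pc([("Chr1", 10, "SAME")])
        chroms = ChromosomeSet([("Chr1", 100), ("Chr2", 250)])
        series = bin_counts(pc, Metric.SAME, 100, chroms)
        by = {s.chrom: s for s in series}
        assert by["Chr2"].counts.tolist() == [0, 0, 0]

    def test_single_bin_when_bin_size_exceeds_length(self):
        pc = _pc([("Chr1", 10, "SAME")])
        chroms = ChromosomeSet([("Chr1", 100)])
        (series,) = bin_counts(pc, Metric.SAME, 10_000, chroms)
        assert series.counts.tolist() == [1]

    def test_conservation_on_simulated_pairs(self, noisy_sim):
        ds, _ = noisy_sim
        for bin_size in (500_000, 137_001):
            for comp in ("F2", "D1"):
                pc = compare_pair(ds, "F1", comp)
                total = bin_counts(pc, Metric.TOTAL, bin_size, ds.chromosomes)
                same = bin_counts(pc, Metric.SAME, bin_size, ds.chromosomes)
                diff = bin_counts(pc, Metric.DIFFERENT, bin_size, ds.chromosomes)
                for t, s, d in zip(total, same, diff):
                    assert (s.counts + d.counts == t.counts).all()
                n_counted = sum(int(t.counts.sum()) for t in total)
                assert n_counted == ds.n_sites - pc.counts()[Verdict.MISSING]

    def test_halving_bin_size_preserves_per_chromosome_sums(self, noisy_sim):
        ds, _ = noisy_sim
        pc = compare_pair(ds, "F1", "D1")
        coarse = bin_counts(pc, Metric.DIFFERENT, 500_000, ds.chromosomes)
        fine = bin_counts(pc, Metric.DIFFERENT, 250_000, ds.chromosomes)
        for c, f in zip(coarse, fine):
            assert c.counts.sum() == f.counts.sum()


def _series(counts_per_chrom, bin_size=10):
    return [
        BinSeries(
            chrom=f"Chr{i + 1}",
            chrom_length=len(c) * bin_size,
            bin_size=bin_size,
            counts=np.array(c),
            metric=Metric.DIFFERENT,
            pair=("R", "C"),
        )
        for i, c in enumerate(counts_per_chrom)
    ]


class TestScaling:
    def test_affine_normalization(self):
        (scaled,) = scale_histogram(_series([[0, 5, 10]]))
        assert scaled.values.tolist() == [0.0, 0.5, 1.0]
        assert (scaled.scale_min, scaled.scale_max) == (0.0, 10.0)

    def test_minmax_is_genome_wide_not_per_chromosome(self):
        a, b = scale_histogram(_series([[0, 4], [8, 2]]))
        assert a.values.tolist() == [0.0, 0.5]
        assert b.values.tolist() == [1.0, 0.25]

    def test_flat_track_scales_to_zero(self):
        (scaled,) = scale_histogram(_series([[7, 7, 7]]))
        assert scaled.values.tolist() == [0.0, 0.0, 0.0]

    def test_user_max_clamps_higher_counts(self):
        (scaled,) = scale_histogram(_series([[0, 45]]), user_min=0, user_max=30)
        assert scaled.values.tolist() == [0.0, 1.0]

    def test_inverted_user_range_rejected(self):
        with pytest.raises(ValueError, match="min.*max"):
            scale_histogram(_series([[1, 2]]), user_min=10, user_max=5)

    def test_rescaling_with_same_bounds_is_idempotent(self):
        series = _series([[0, 3, 9, 6]])
        first = scale_histogram(series, user_min=0, user_max=9)
        second = scale_histogram(series, user_min=0, user_max=9)
        assert np.array_equal(first[0].values, second[0].values)


class TestHeatmap:
    def test_endpoints_map_to_ramp_ends(self):
        (scaled,) = scale_heatmap(_series([[0, 10]]), ramp=("#000000", "#ff0000"))
        assert scaled.colors == ["#000000", "#ff0000"]

    def test_midpoint_interpolates_channel_wise(self):
        assert interpolate_ramp(0.5, ("#000000", "#ff6400")) == "#803200"

    def test_three_stop_ramp_passes_through_middle_color(self):
        assert interpolate_ramp(0.5, ("#000000", "#123456", "#ffffff")) == "#123456"

    def test_flat_counts_render_uniform_first_color(self):
        (scaled,) = scale_heatmap(_series([[4, 4, 4]]), ramp=("#ffffff", "#cc0000"))
        assert set(scaled.colors) == {"#ffffff"}

    def test_short_ramp_rejected(self):
        with pytest.raises(ValueError, match="2 colors"):
            scale_heatmap(_series([[1]]), ramp=("#ffffff",))


class TestHaplotype:
    def test_threshold_is_inclusive(self):
        (scaled,) = haplotype_presence(_series([[0, 4, 5, 9]]), threshold=5)
        assert scaled.values.tolist() == [False, False, True, True]

    def test_threshold_boundaries(self):
        series = _series([[0, 4, 5, 9]])
        assert haplotype_presence(series, 0)[0].values.all()
        assert not haplotype_presence(series, 10)[0].values.any()

    @settings(max_examples=50, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 50), min_size=1, max_size=30),
        t1=st.integers(0, 50),
        t2=st.integers(0, 50),
    )
    def test_presence_is_monotone_in_threshold(self, counts, t1, t2):
        lo, hi = sorted((t1, t2))
        series = _series([counts])
        at_hi = haplotype_presence(series, hi)[0].values
        at_lo = haplotype_presence(series, lo)[0].values
        assert not (at_hi & ~at_lo).any()  # present at hi => present at lo
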