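"""Aggregate site classifications into fixed genomic bins and scale for display.

Bins are 1-based inclusive windows of ``bin_size`` bp: bin k covers
[k*bin_size + 1, (k+1)*bin_size], the last bin truncated at the chromosome
length. The default bin size is 500 kb.

Three display transformations operate on the per-chromosome count arrays of
one track (one pair + one metric):

* histogram — affine min-max normalization to [0, 1], where min/max are taken
  across the entire genome (all bins of all chromosomes of the track) unless
  the user supplies them; out-of-range counts clamp.
* heatmap — the same normalization, then linear interpolation along a color
  ramp.
* haplotype — boolean presence: count >= threshold.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .model import BinSeries, ChromosomeSet, Metric, PairComparison, ScaledSeries, Verdict


def assign_bin(pos: int, bin_size: int) -> int:
    """Bin index of a 1-based position: floor((pos-1)/bin_size)."""
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    return (pos - 1) // bin_size


def n_bins(chrom_length: int, bin_size: int) -> int:
    """Number of bins covering a chromosome: ceil(length / bin_size)."""
    return -(-chrom_length // bin_size)


def bin_counts(
    comparison: PairComparison,
    metric: Metric,
    bin_size: int,
    chromosomes: ChromosomeSet,
) -> list[BinSeries]:
    """Count qualifying sites per bin, one series per chromosome.

    ``Metric.TOTAL`` counts sites with verdict SAME or DIFFERENT (sites where
    both accessions are called); MISSING sites are never counted. Chromosomes
    with no qualifying sites get an all-zero series of the correct length.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    counts = {
        name: np.zeros(n_bins(length, bin_size), dtype=np.int64)
        for name, length in chromosomes
    }
    if metric is Metric.TOTAL:
        wanted = {Verdict.SAME, Verdict.DIFFERENT}
    else:
        wanted = {Verdict[metric.value]}
    for cls in comparison.classifications:
        if cls.verdict in wanted:
            counts[cls.chrom][assign_bin(cls.pos, bin_size)] += 1
    pair = (comparison.ref_sample, comparison.comp_sample)
    return [
        BinSeries(
            chrom=name,
            chrom_length=length,
            bin_size=bin_size,
            counts=counts[name],
            metric=metric,
            pair=pair,
        )
        for name, length in chromosomes
    ]


def _resolve_scale(
    series: Sequence[BinSeries],
    user_min: Optional[float],
    user_max: Optional[float],
) -> tuple[float, float]:
    if not series or all(s.n_bins == 0 for s in series):
        raise ValueError("cannot scale a track with no bins")
    if user_min is not None and user_max is not None and user_min >= user_max:
        raise ValueError(f"min ({user_min}) must be below max ({user_max})")
    allc = np.concatenate([s.counts for s in series])
    lo = float(allc.min()) if user_min is None else float(user_min)
    hi = float(allc.max()) if user_max is None else float(user_max)
    return lo, hi


def scale_histogram(
    series: Sequence[BinSeries],
    user_min: Optional[float] = None,
    user_max: Optional[float] = None,
) -> list[ScaledSeries]:
    """Normalize one track's counts to [0, 1] bar lengths.

    value = (count - m) / (M - m) clamped to [0, 1], with m and M the
    genome-wide min and max over all bins of the track unless supplied by the
    user. If M == m every value is 0 (a flat track draws no bars).
    """
    lo, hi = _resolve_scale(series, user_min, user_max)
    out = []
    for s in series:
        if hi == lo:
            vals = np.zeros(s.n_bins, dtype=float)
        else:
            vals = np.clip((s.counts - lo) / (hi - lo), 0.0, 1.0)
        out.append(ScaledSeries(source=s, values=vals, scale_min=lo, scale_max=hi))
    return out


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    c = color.lstrip("#")
    if len(c) != 6:
        raise ValueError(f"expected #rrggbb hex color, got {color!r}")
    return tuple(int(c[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def _rgb_to_hex(rgb: Sequence[float]) -> str:
    return "#%02x%02x%02x" % tuple(int(round(v)) for v in rgb)


def interpolate_ramp(value: float, ramp: Sequence[str]) -> str:
    """Map a value in [0, 1] to a color by channel-wise linear interpolation."""
    if len(ramp) < 2:
        raise ValueError("color ramp needs at least 2 colors")
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"value {value} outside [0, 1]")
    stops = [np.array(_hex_to_rgb(c), dtype=float) for c in ramp]
    x = value * (len(stops) - 1)
    i = min(int(x), len(stops) - 2)
    frac = x - i
    return _rgb_to_hex(stops[i] * (1 - frac) + stops[i + 1] * frac)


def scale_heatmap(
    series: Sequence[BinSeries],
    user_min: Optional[float] = None,
    user_max: Optional[float] = None,
    ramp: Sequence[str] = ("#ffffff", "#cc0000"),
) -> list[ScaledSeries]:
    """Histogram normalization followed by color-ramp lookup per bin."""
    scaled = scale_histogram(series, user_min=user_min, user_max=user_max)
    for s in scaled:
        s.colors = [interpolate_ramp(float(v), ramp) for v in s.values]
    return scaled


def haplotype_presence(
    series: Sequence[BinSeries], threshold: int
) -> list[ScaledSeries]:
    """Boolean presence per bin: count >= threshold."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return [
        ScaledSeries(source=s, values=s.counts >= threshold, threshold=threshold)
        for s in series
    ]
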