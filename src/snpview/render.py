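"""Whole-genome figure rendering: backbones, ruler, tracks, key, title.

Chromosomes are drawn as vertical backbones side by side at a uniform
bp-to-pixel scale. Each comparison track occupies a fixed-width band on the
left or right of every backbone:

* histogram — horizontal bars whose length is the scaled value times the band
  width (zero-length bars are not drawn);
* heatmap — one fixed-width cell per bin, filled with the ramp color;
* haplotype — a solid cell of the track color drawn only where present.

Output is SVG 1.1 built as deterministic text: identical inputs produce
byte-identical documents. :func:`rasterize` converts that SVG to PNG with a
small built-in renderer (lxml + Pillow) covering exactly the element subset
this module emits (rect, line, text).

An optional static annotation layer (e.g. centromeres) can be overlaid on the
backbones from a 3-column BED file.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from lxml import etree
from PIL import Image, ImageDraw

from . import binning
from .compare import compare_pair
from .model import (
    BinReport,
    BinSeries,
    ChromosomeSet,
    ScaledSeries,
    TrackSpec,
    VariantDataset,
    ViewSpec,
)

PathLike = Union[str, Path]

# Geometry defaults (px). The paper-style figure is parameterized here, not
# user-facing: a desk-scale figure rarely needs to change them.
DRAW_HEIGHT = 600.0  # pixel height of the longest chromosome
BACKBONE_WIDTH = 6.0
TRACK_WIDTH = 40.0  # max histogram bar length == heatmap/haplotype cell width
TRACK_GAP = 3.0
SLOT_PAD = 18.0  # horizontal padding between chromosome slots
MARGIN = 40.0
TITLE_HEIGHT = 30.0
KEY_LINE_HEIGHT = 18.0
RULER_WIDTH = 46.0
FONT_SIZE = 11.0


@dataclass
class Layout:
    """Resolved figure geometry."""

    width: float
    height: float
    px_per_bp: float
    y0: float  # top of the chromosome drawing area
    chrom_x: dict[str, float]  # chromosome -> backbone left-edge x
    chromosomes: ChromosomeSet
    ruler_tics: list[int]  # bp positions of labeled tics (multiples of interval)
    left_offsets: list[float]  # band offsets from backbone per left-side track
    right_offsets: list[float]
    key_y: float


def _side_offsets(tracks: Sequence[TrackSpec]) -> tuple[list[float], list[float]]:
    left, right = [], []
    for t in tracks:
        if t.side == "left":
            left.append(BACKBONE_WIDTH / 2 + TRACK_GAP + len(left) * (TRACK_WIDTH + TRACK_GAP))
        else:
            right.append(BACKBONE_WIDTH / 2 + TRACK_GAP + len(right) * (TRACK_WIDTH + TRACK_GAP))
    return left, right


def layout_genome(chromosomes: ChromosomeSet, spec: ViewSpec) -> Layout:
    """Compute figure geometry for a chromosome set under a view spec.

    Emits a warning when a bin would round below one pixel at the chosen
    scale, since such data cannot be displayed faithfully — use a larger bin
    size.
    """
    if spec.chromosome_filter:
        chromosomes = chromosomes.subset(spec.chromosome_filter)
    if len(chromosomes) == 0:
        raise ValueError("no chromosomes to lay out")

    max_len = max(length for _, length in chromosomes)
    px_per_bp = DRAW_HEIGHT / max_len
    if spec.bin_size * px_per_bp < 1.0:
        warnings.warn(
            f"bin size {spec.bin_size} bp maps to less than one pixel at this "
            "scale; increase the bin size for a faithful display",
            stacklevel=2,
        )
    if spec.ruler_interval < spec.bin_size:
        warnings.warn(
            "ruler interval below the bin size produces denser tics than bins",
            stacklevel=2,
        )

    left, right = _side_offsets(spec.tracks)
    half_left = (max(left) + TRACK_WIDTH) if left else BACKBONE_WIDTH / 2
    half_right = (max(right) + TRACK_WIDTH) if right else BACKBONE_WIDTH / 2
    slot_width = half_left + half_right + SLOT_PAD

    n_ruler = {"left": 1, "right": 1, "both": 2}[spec.ruler_side]
    title_h = TITLE_HEIGHT if spec.title else 0.0
    y0 = MARGIN + title_h
    x = MARGIN + (RULER_WIDTH if spec.ruler_side in ("left", "both") else 0.0)

    chrom_x: dict[str, float] = {}
    for name, _length in chromosomes:
        chrom_x[name] = x + half_left
        x += slot_width
    if spec.ruler_side in ("right", "both"):
        x += RULER_WIDTH

    comps = {(t.ref_sample, t.comp_sample) for t in spec.tracks}
    key_rows = len(spec.tracks)
    key_y = y0 + DRAW_HEIGHT + 2 * KEY_LINE_HEIGHT
    height = key_y + key_rows * KEY_LINE_HEIGHT + MARGIN
    width = x + MARGIN

    tics = list(range(spec.ruler_interval, max_len + 1, spec.ruler_interval))
    return Layout(
        width=width,
        height=height,
        px_per_bp=px_per_bp,
        y0=y0,
        chrom_x=chrom_x,
        chromosomes=chromosomes,
        ruler_tics=tics,
        left_offsets=left,
        right_offsets=right,
        key_y=key_y,
    )


def _fmt(x: float) -> str:
    """Fixed decimal formatting keeps the SVG byte-deterministic."""
    return f"{x:.3f}".rstrip("0").rstrip(".")


def _rect(x: float, y: float, w: float, h: float, fill: str, extra: str = "") -> str:
    return (
        f'<rect x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(w)}" '
        f'height="{_fmt(h)}" fill="{fill}"{extra}/>'
    )


def _line(x1: float, y1: float, x2: float, y2: float, stroke: str = "#000000") -> str:
    return (
        f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
        f'stroke="{stroke}" stroke-width="1"/>'
    )


def _text(x: float, y: float, s: str, anchor: str = "start", size: float = FONT_SIZE) -> str:
    return (
        f'<text x="{_fmt(x)}" y="{_fmt(y)}" font-family="sans-serif" '
        f'font-size="{_fmt(size)}" text-anchor="{anchor}">{_escape(s)}</text>'
    )


def _escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _ruler(lines: list[str], layout: Layout, x: float, label_side: str) -> None:
    max_len = max(length for _, length in layout.chromosomes)
    y_top, y_bot = layout.y0, layout.y0 + max_len * layout.px_per_bp
    lines.append(_line(x, y_top, x, y_bot))
    anchor = "end" if label_side == "left" else "start"
    dx = -4.0 if label_side == "left" else 4.0
    lines.append(_text(x + dx, y_top + 4, "0", anchor=anchor))
    for bp in layout.ruler_tics:
        y = layout.y0 + bp * layout.px_per_bp
        lines.append(_line(x - 3, y, x + 3, y))
        lines.append(_text(x + dx, y + 4, f"{bp / 1e6:.1f} Mb", anchor=anchor))


def load_bed(path: PathLike) -> list[tuple[str, int, int]]:
    """Read a 3-column BED file into 1-based inclusive intervals."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
        chrom, start0, end0 = cols[0], int(cols[1]), int(cols[2])
        if end0 <= start0:
            raise ValueError(f"{path}: line {lineno}: empty or inverted interval")
        out.append((chrom, start0 + 1, end0))
    return out


def build_tracks(dataset: VariantDataset, spec: ViewSpec) -> list[list[BinSeries]]:
    """Run the comparison + binning pipeline for every track of a view."""
    chroms = dataset.chromosomes
    if spec.chromosome_filter:
        chroms = chroms.subset(spec.chromosome_filter)
    out = []
    cache: dict[tuple[str, str], object] = {}
    for t in spec.tracks:
        key = (t.ref_sample, t.comp_sample)
        if key not in cache:
            cache[key] = compare_pair(dataset, *key)
        out.append(binning.bin_counts(cache[key], t.metric, spec.bin_size, chroms))
    return out


def scale_tracks(
    track_series: Sequence[Sequence[BinSeries]], spec: ViewSpec
) -> list[list[ScaledSeries]]:
    """Apply each track's display transformation to its binned counts."""
    scaled = []
    for t, series in zip(spec.tracks, track_series):
        if t.display == "histogram":
            scaled.append(binning.scale_histogram(series, t.user_min, t.user_max))
        elif t.display == "heatmap":
            scaled.append(
                binning.scale_heatmap(
                    series, t.user_min, t.user_max, ramp=("#ffffff", t.color)
                )
            )
        else:
            scaled.append(binning.haplotype_presence(series, t.threshold or 1))
    return scaled


def render_svg(
    scaled_tracks: Sequence[Sequence[ScaledSeries]],
    spec: ViewSpec,
    annotations: Optional[Sequence[tuple[str, int, int]]] = None,
) -> str:
    """Draw the figure as an SVG 1.1 document (deterministic text).

    ``scaled_tracks`` holds, per TrackSpec of the view, one ScaledSeries per
    chromosome. All tracks must share the bin size and chromosome set.
    """
    if len(scaled_tracks) != len(spec.tracks):
        raise ValueError("one ScaledSeries set per TrackSpec is required")
    bin_sizes = {s.source.bin_size for track in scaled_tracks for s in track}
    if len(bin_sizes) > 1:
        raise ValueError(f"mixed bin sizes across tracks: {sorted(bin_sizes)}")
    chrom_sets = {
        tuple((s.source.chrom, s.source.chrom_length) for s in track)
        for track in scaled_tracks
    }
    if len(chrom_sets) > 1:
        raise ValueError("tracks cover different chromosome sets")
    chromosomes = ChromosomeSet([list(cs) for cs in chrom_sets][0])

    layout = layout_genome(chromosomes, spec)
    ppb = layout.px_per_bp
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(layout.width)}" height="{_fmt(layout.height)}" '
        f'viewBox="0 0 {_fmt(layout.width)} {_fmt(layout.height)}">',
        f'<rect x="0" y="0" width="{_fmt(layout.width)}" '
        f'height="{_fmt(layout.height)}" fill="#ffffff"/>',
    ]
    if spec.title:
        lines.append(
            _text(layout.width / 2, MARGIN, spec.title, anchor="middle", size=16)
        )

    # Rulers
    if spec.ruler_side in ("left", "both"):
        _ruler(lines, layout, MARGIN + RULER_WIDTH - 6, "left")
    if spec.ruler_side in ("right", "both"):
        _ruler(lines, layout, layout.width - MARGIN - RULER_WIDTH + 6, "right")

    # Backbones + chromosome labels
    lines.append('<g id="backbones">')
    for name, length in layout.chromosomes:
        x = layout.chrom_x[name]
        lines.append(
            _rect(x - BACKBONE_WIDTH / 2, layout.y0, BACKBONE_WIDTH,
                  length * ppb, "#b0b0b0")
        )
        lines.append(_text(x, layout.y0 - 8, name, anchor="middle"))
    lines.append("</g>")

    # Annotation overlay (e.g. centromeres) on the backbones
    if annotations:
        lines.append('<g id="annotations">')
        for chrom, start, end in annotations:
            if chrom not in layout.chrom_x:
                continue
            x = layout.chrom_x[chrom]
            y = layout.y0 + (start - 1) * ppb
            h = max((end - start + 1) * ppb, 1.0)
            lines.append(_rect(x - BACKBONE_WIDTH, y, BACKBONE_WIDTH * 2, h, "#555555"))
        lines.append("</g>")

    # Tracks
    li = ri = 0
    for ti, (tspec, track) in enumerate(zip(spec.tracks, scaled_tracks)):
        if tspec.side == "left":
            offset = layout.left_offsets[li]
            li += 1
        else:
            offset = layout.right_offsets[ri]
            ri += 1
        for series in track:
            chrom = series.source.chrom
            x0 = layout.chrom_x[chrom]
            lines.append(f'<g id="track{ti}_{chrom}">')
            for k in range(series.source.n_bins):
                start, end = series.source.bin_interval(k)
                y = layout.y0 + (start - 1) * ppb
                h = (end - start + 1) * ppb
                if tspec.display == "histogram":
                    v = float(series.values[k])
                    if v <= 0:
                        continue  # zero-length bars are suppressed
                    w = v * TRACK_WIDTH
                    x = x0 - offset - w if tspec.side == "left" else x0 + offset
                    lines.append(_rect(x, y, w, h, tspec.color))
                elif tspec.display == "heatmap":
                    x = x0 - offset - TRACK_WIDTH if tspec.side == "left" else x0 + offset
                    lines.append(_rect(x, y, TRACK_WIDTH, h, series.colors[k]))
                else:  # haplotype
                    if not bool(series.values[k]):
                        continue
                    x = x0 - offset - TRACK_WIDTH if tspec.side == "left" else x0 + offset
                    lines.append(_rect(x, y, TRACK_WIDTH, h, tspec.color))
            lines.append("</g>")

    # Key: one row per track, swatch + description
    lines.append('<g id="key">')
    lines.append(_text(MARGIN, layout.key_y - 6, "Key", size=12))
    for i, tspec in enumerate(spec.tracks):
        y = layout.key_y + i * KEY_LINE_HEIGHT
        lines.append(_rect(MARGIN, y, 12, 12, tspec.color))
        label = (
            f"{tspec.comp_sample} vs {tspec.ref_sample} "
            f"({tspec.metric.value.lower()}, {tspec.display}, {tspec.side})"
        )
        lines.append(_text(MARGIN + 18, y + 10, label))
    lines.append("</g>")

    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def rasterize(svg: str, scale: float = 1.0) -> bytes:
    """Convert an SVG document produced by :func:`render_svg` to PNG bytes.

    PNG dimensions are the SVG width/height multiplied by ``scale``. Only the
    element subset this package emits (rect, line, text, nested g) is drawn.
    """
    try:
        root = etree.fromstring(svg.encode())
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"invalid SVG: {exc}") from exc
    if etree.QName(root).localname != "svg":
        raise ValueError("invalid SVG: root element is not <svg>")
    try:
        width = float(root.get("width"))
        height = float(root.get("height"))
    except (TypeError, ValueError):
        raise ValueError("invalid SVG: missing numeric width/height") from None

    w, h = int(round(width * scale)), int(round(height * scale))
    img = Image.new("RGB", (w, h), "#ffffff")
    draw = ImageDraw.Draw(img)

    def walk(el):
        tag = etree.QName(el).localname
        if tag == "rect":
            x, y = float(el.get("x")) * scale, float(el.get("y")) * scale
            rw, rh = float(el.get("width")) * scale, float(el.get("height")) * scale
            fill = el.get("fill", "#000000")
            if fill != "none":
                draw.rectangle([x, y, x + max(rw, 1e-9), y + max(rh, 1e-9)], fill=fill)
        elif tag == "line":
            pts = [
                float(el.get("x1")) * scale,
                float(el.get("y1")) * scale,
                float(el.get("x2")) * scale,
                float(el.get("y2")) * scale,
            ]
            draw.line(pts, fill=el.get("stroke", "#000000"),
                      width=max(1, int(round(scale))))
        elif tag == "text":
            x, y = float(el.get("x")) * scale, float(el.get("y")) * scale
            anchor = {"start": "ls", "middle": "ms", "end": "rs"}.get(
                el.get("text-anchor", "start"), "ls"
            )
            draw.text((x, y), el.text or "", fill="#000000", anchor=anchor)
        for child in el:
            walk(child)

    walk(root)
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()


def bin_report(
    tracks: Sequence[BinSeries],
    chrom: str,
    bin_index: int,
    totals: Optional[Sequence[BinSeries]] = None,
) -> BinReport:
    """Report one bin: coordinates plus raw per-accession counts and the total.

    ``tracks`` are the displayed series (all chromosomes or just ``chrom``);
    ``totals``, when given, are TOTAL-metric series used for the bin's total.
    Without ``totals`` the total falls back to the sum of displayed values.
    """
    here = [s for s in tracks if s.chrom == chrom]
    if not here:
        raise ValueError(f"no track covers chromosome {chrom!r}")
    nb = here[0].n_bins
    if not 0 <= bin_index < nb:
        raise IndexError(
            f"bin {bin_index} out of range for {chrom} (valid: 0..{nb - 1})"
        )
    start, end = here[0].bin_interval(bin_index)
    values = {s.pair[1]: int(s.counts[bin_index]) for s in here}
    if totals is not None:
        total = sum(
            int(s.counts[bin_index]) for s in totals if s.chrom == chrom
        )
    else:
        total = sum(values.values())
    return BinReport(
        chrom=chrom, bin_index=bin_index, start=start, end=end,
        values=values, total=total,
    )


def render_view(
    dataset: VariantDataset,
    spec: ViewSpec,
    annotations: Optional[Sequence[tuple[str, int, int]]] = None,
) -> str:
    """One-shot pipeline: compare, bin, scale and render a dataset view."""
    series = build_tracks(dataset, spec)
    return render_svg(scale_tracks(series, spec), spec, annotations=annotations)
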