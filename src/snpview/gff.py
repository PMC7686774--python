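"""Serialize binned comparison tracks to GFF3 and read them back.

The GFF3 file is the downloadable intermediate that fully describes a figure:
one feature per bin per track (zero-count bins included), raw count in the
score column, and the pair/metric/bin bookkeeping in the attributes column.
The dialect is stable and documented here; it is not claimed bit-identical to
any other tool's GFF output.

Columns: seqid, source=``snpview``, type=``comparison_bin``, start, end,
score=<count>, strand=., phase=., attributes
``ID=<comp>_<metric>_<chrom>_<bin>;ref=<ref>;sample=<comp>;metric=<metric>;bin=<k>``.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .model import BinSeries, Metric

PathLike = Union[str, Path]

_SOURCE = "snpview"
_TYPE = "comparison_bin"


def write_gff(tracks: Sequence[BinSeries], path: PathLike) -> None:
    """Write one feature line per bin per track, preceded by the GFF3 header."""
    if not tracks:
        raise ValueError("no tracks to write")
    lines = ["##gff-version 3"]
    for series in tracks:
        ref, comp = series.pair
        for k in range(series.n_bins):
            start, end = series.bin_interval(k)
            attrs = (
                f"ID={comp}_{series.metric.value}_{series.chrom}_{k};"
                f"ref={ref};sample={comp};metric={series.metric.value};bin={k}"
            )
            lines.append(
                f"{series.chrom}\t{_SOURCE}\t{_TYPE}\t{start}\t{end}\t"
                f"{int(series.counts[k])}\t.\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attributes(field: str, lineno: int) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"line {lineno}: malformed attribute {part!r}")
        key, _, value = part.partition("=")
        out[key] = value
    return out


def read_gff(path: PathLike) -> list[BinSeries]:
    """Reconstruct the BinSeries set written by :func:`write_gff`.

    The bin size is inferred from the modal feature span (the final bin of a
    chromosome may be truncated, so the most common span is the true size).
    """
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("##gff-version 3"):
        raise ValueError(f"{path}: not a GFF3 file (missing ##gff-version 3 header)")

    # (pair, metric, chrom) -> {bin index: (start, end, count)}
    groups: dict[tuple[tuple[str, str], Metric, str], dict[int, tuple[int, int, int]]]
    groups = defaultdict(dict)
    order: list[tuple[tuple[str, str], Metric, str]] = []
    spans: Counter[int] = Counter()

    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(
                f"{path}: line {lineno}: expected 9 tab-separated columns, "
                f"got {len(cols)} (last good line: {lineno - 1})"
            )
        seqid, _, _, start_s, end_s, score_s, _, _, attr_s = cols
        try:
            start, end, score = int(start_s), int(end_s), int(score_s)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        attrs = _parse_attributes(attr_s, lineno)
        for required in ("ref", "sample", "metric", "bin"):
            if required not in attrs:
                raise ValueError(
                    f"{path}: line {lineno}: missing required attribute {required!r}"
                )
        try:
            metric = Metric(attrs["metric"])
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: unknown metric {attrs['metric']!r}"
            ) from None
        key = ((attrs["ref"], attrs["sample"]), metric, seqid)
        if key not in groups:
            order.append(key)
        groups[key][int(attrs["bin"])] = (start, end, score)
        spans[end - start + 1] += 1

    if not groups:
        raise ValueError(f"{path}: no feature lines found")

    # Modal span = bin size (ties broken toward the larger span, since only
    # final bins can be truncated short).
    top = max(spans.values())
    bin_size = max(s for s, c in spans.items() if c == top)

    out: list[BinSeries] = []
    for pair, metric, chrom in order:
        bins = groups[(pair, metric, chrom)]
        nb = max(bins) + 1
        if sorted(bins) != list(range(nb)):
            raise ValueError(
                f"{path}: track {pair}/{metric.value}/{chrom} has missing bins"
            )
        counts = np.zeros(nb, dtype=np.int64)
        for k, (start, end, score) in bins.items():
            expected_start = k * bin_size + 1
            if start != expected_start:
                raise ValueError(
                    f"{path}: bin {k} of {chrom} starts at {start}, "
                    f"expected {expected_start} for bin size {bin_size}"
                )
            counts[k] = score
        chrom_length = bins[nb - 1][1]  # end of final bin == chromosome length
        out.append(
            BinSeries(
                chrom=chrom,
                chrom_length=chrom_length,
                bin_size=bin_size,
                counts=counts,
                metric=metric,
                pair=pair,
            )
        )
    return out
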