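"""Core data model: genotype calls, variant sites, datasets and track containers.

An *accession* (germplasm line) is one sample column of a multi-sample VCF.
All comparisons in this package are between a user-chosen reference accession
and one or more comparison accessions within a single dataset.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np


class Verdict(enum.Enum):
    """Per-site classification of a (reference, comparison) genotype pair."""

    SAME = "SAME"
    DIFFERENT = "DIFFERENT"
    MISSING = "MISSING"


class Metric(enum.Enum):
    """Which sites a binned track counts.

    TOTAL counts sites where both accessions are called (SAME or DIFFERENT),
    i.e. the sites actually usable in the comparison; MISSING sites are never
    counted by any metric.
    """

    SAME = "SAME"
    DIFFERENT = "DIFFERENT"
    TOTAL = "TOTAL"


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site.

    ``alleles`` is an unordered multiset of allele indices, stored as a sorted
    tuple (0 = REF, 1.. = ALT). Phase is deliberately discarded: ``0|1`` and
    ``1/0`` produce the identical call. A call with any unknown allele
    (``.``), including half-calls like ``0/.``, is missing and has an empty
    allele tuple.
    """

    alleles: tuple[int, ...]
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing and self.alleles:
            raise ValueError("missing call must have empty alleles")
        if not self.missing and not self.alleles:
            raise ValueError("non-missing call must carry at least one allele")
        if any(a < 0 for a in self.alleles):
            raise ValueError("allele indices must be >= 0")
        if tuple(sorted(self.alleles)) != self.alleles:
            object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @classmethod
    def from_indices(cls, indices: Iterable[int]) -> "GenotypeCall":
        """Build a call from raw allele indices; any negative index => missing."""
        idx = list(indices)
        if any(i < 0 for i in idx) or not idx:
            return cls(alleles=(), missing=True)
        return cls(alleles=tuple(sorted(idx)), missing=False)

    @property
    def ploidy(self) -> Optional[int]:
        return None if self.missing else len(self.alleles)


@dataclass
class VariantSite:
    """One variant record: coordinates, alleles, quality and per-sample calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    calls: dict[str, GenotypeCall]
    qual: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos} on {self.chrom}")
        if self.qual is not None and self.qual < 0:
            raise ValueError(f"negative QUAL at {self.chrom}:{self.pos}")
        n_alleles = 1 + len(self.alts)
        for sample, call in self.calls.items():
            if not call.missing and any(a >= n_alleles for a in call.alleles):
                raise ValueError(
                    f"allele index out of range for sample {sample} at "
                    f"{self.chrom}:{self.pos} ({call.alleles}, {n_alleles} alleles)"
                )


@dataclass
class ChromosomeSet:
    """Ordered chromosome names with lengths in bp.

    Lengths come from ``##contig`` header lines when present, otherwise from
    the maximum observed site position per chromosome.
    """

    entries: list[tuple[str, int]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.entries:
            if length < 1:
                raise ValueError(f"chromosome {name} has non-positive length")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def length(self, name: str) -> int:
        for n, ln in self.entries:
            if n == name:
                return ln
        raise KeyError(f"unknown chromosome {name!r}; known: {self.names}")

    def __contains__(self, name: object) -> bool:
        return any(n == name for n, _ in self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, names: Sequence[str]) -> "ChromosomeSet":
        keep = [e for e in self.entries if e[0] in set(names)]
        if not keep:
            raise ValueError(f"no chromosomes left after filtering to {list(names)}")
        return ChromosomeSet(keep)


@dataclass
class VariantDataset:
    """Ordered variant sites x named samples, with chromosome metadata.

    Sites are strictly sorted by (chromosome order, position); duplicate
    (chrom, pos) pairs are rejected. Comparisons are only meaningful within a
    single dataset (one reference genome assembly).
    """

    samples: list[str]
    sites: list[VariantSite]
    chromosomes: ChromosomeSet

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("dataset has no samples")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names")
        order = {name: i for i, (name, _) in enumerate(self.chromosomes.entries)}
        prev = None
        for site in self.sites:
            if site.chrom not in order:
                raise ValueError(
                    f"site {site.chrom}:{site.pos} on chromosome absent from the chromosome set"
                )
            if site.pos > self.chromosomes.length(site.chrom):
                raise ValueError(
                    f"site {site.chrom}:{site.pos} beyond chromosome length "
                    f"{self.chromosomes.length(site.chrom)}"
                )
            key = (order[site.chrom], site.pos)
            if prev is not None and key <= prev:
                raise ValueError(
                    f"sites not strictly sorted at {site.chrom}:{site.pos}; "
                    "sort the input (e.g. bcftools sort) and remove duplicates"
                )
            prev = key
            missing_samples = set(self.samples) - set(site.calls)
            if missing_samples:
                raise ValueError(
                    f"site {site.chrom}:{site.pos} lacks calls for {sorted(missing_samples)}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def require_sample(self, name: str) -> None:
        if name not in self.samples:
            raise KeyError(
                f"unknown sample {name!r}; available samples: {', '.join(self.samples)}"
            )


@dataclass(frozen=True)
class SiteClassification:
    chrom: str
    pos: int
    verdict: Verdict


@dataclass
class PairComparison:
    """All site classifications for one (reference, comparison) accession pair."""

    ref_sample: str
    comp_sample: str
    classifications: list[SiteClassification]

    def counts(self) -> dict[Verdict, int]:
        out = {v: 0 for v in Verdict}
        for c in self.classifications:
            out[c.verdict] += 1
        return out


@dataclass
class BinSeries:
    """Per-bin counts of one metric for one pair on one chromosome.

    Bin k spans the 1-based inclusive interval [k*bin_size + 1, (k+1)*bin_size],
    the final bin truncated at the chromosome length.
    """

    chrom: str
    chrom_length: int
    bin_size: int
    counts: np.ndarray  # int array, len == ceil(chrom_length / bin_size)
    metric: Metric
    pair: tuple[str, str]  # (ref_sample, comp_sample)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = -(-self.chrom_length // self.bin_size)
        if len(self.counts) != expected:
            raise ValueError(
                f"{self.chrom}: counts length {len(self.counts)} != "
                f"ceil({self.chrom_length}/{self.bin_size}) = {expected}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative bin counts")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_interval(self, k: int) -> tuple[int, int]:
        """1-based inclusive (start, end) of bin k, truncated at chrom length."""
        if not 0 <= k < self.n_bins:
            raise IndexError(
                f"bin {k} out of range for {self.chrom} (valid: 0..{self.n_bins - 1})"
            )
        start = k * self.bin_size + 1
        end = min((k + 1) * self.bin_size, self.chrom_length)
        return start, end


@dataclass
class ScaledSeries:
    """A BinSeries after display-type transformation.

    Histogram/heatmap: ``values`` in [0, 1] via affine min-max normalization.
    Haplotype: ``values`` boolean (count >= threshold).
    """

    source: BinSeries
    values: np.ndarray
    scale_min: Optional[float] = None
    scale_max: Optional[float] = None
    threshold: Optional[int] = None
    colors: Optional[list[str]] = None  # per-bin hex colors (heatmap only)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if len(self.values) != self.source.n_bins:
            raise ValueError("values length differs from source bin count")
        if self.values.dtype != bool:
            if ((self.values < 0) | (self.values > 1)).any():
                raise ValueError("scaled values must lie in [0, 1]")


@dataclass
class TrackSpec:
    """How one comparison track is displayed alongside the backbones."""

    ref_sample: str
    comp_sample: str
    metric: Metric = Metric.DIFFERENT
    display: str = "histogram"  # histogram | heatmap | haplotype
    side: str = "right"  # left | right
    color: str = "#cc0000"
    user_min: Optional[float] = None
    user_max: Optional[float] = None
    threshold: Optional[int] = None

    def __post_init__(self) -> None:
        if self.display not in ("histogram", "heatmap", "haplotype"):
            raise ValueError(
                f"unknown display type {self.display!r}; "
                "choose one of histogram, heatmap, haplotype"
            )
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.display == "haplotype":
            if self.user_min is not None or self.user_max is not None:
                raise ValueError("min/max apply to histogram/heatmap, not haplotype")
        else:
            if self.threshold is not None:
                raise ValueError("threshold applies only to the haplotype display")


@dataclass
class ViewSpec:
    """Full description of a figure: tracks, binning, ruler and title."""

    tracks: list[TrackSpec]
    bin_size: int = 500_000  # default bin size: 500 kb
    ruler_interval: int = 5_000_000
    ruler_side: str = "left"  # left | right | both
    title: str = ""
    chromosome_filter: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.ruler_interval < 1:
            raise ValueError("ruler_interval must be >= 1")
        if self.ruler_side not in ("left", "right", "both"):
            raise ValueError("ruler_side must be left, right or both")
        if not self.tracks:
            raise ValueError("a view needs at least one track")


@dataclass
class BinReport:
    """Content of the per-bin report: coordinates plus raw per-accession counts."""

    chrom: str
    bin_index: int
    start: int
    end: int
    values: dict[str, int]  # comparison sample -> raw count at that bin
    total: int
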