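"""Synthetic multi-sample VCF generator with a machine-readable truth ledger.

The generator emulates SNP-array-style genotype panels for a diploid selfing
crop: a handful of *founder* accessions drawn independently under
Hardy-Weinberg equilibrium at a common allele frequency, plus *derived*
accessions assembled by copying founder genotypes block-wise along each
chromosome — the mosaic structure left by introgression breeding or pedigree
descent. Missing calls are injected at a per-sample rate and Phred-like
quality scores are attached per site.

Alongside the dataset the generator records a :class:`TruthLedger`: block
donors per derived sample, forced-missing flags per (site, sample), and the
raw genotypes themselves. :meth:`TruthLedger.expected_bins` recounts per-bin
classifications brute-force from that raw truth, independently of the
comparison/binning pipeline, which makes it the oracle the pipeline is tested
against.

The same seed always yields the same dataset, byte for byte when written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .binning import assign_bin, n_bins
from .model import (
    BinSeries,
    ChromosomeSet,
    GenotypeCall,
    Metric,
    VariantDataset,
    VariantSite,
)

PathLike = Union[str, Path]

_REF_ALLELES = ("A", "C", "G", "T")


@dataclass
class Block:
    """One donor interval of a derived sample (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    donor: str


@dataclass
class SimulationSpec:
    """Everything that determines a synthetic dataset.

    Defaults describe a desk-scale SNP-array panel: 4 chromosomes of 50 Mb,
    2,500 sites per chromosome, 4 founders at allele frequency 0.3, 2%
    missing calls. ``seed`` is mandatory.
    """

    seed: int
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [(f"Chr{i}", 50_000_000) for i in range(1, 5)]
    )
    n_sites: int = 2500  # per chromosome
    n_founders: int = 4
    allele_freq: float = 0.3
    derived: dict[str, list[Block]] = field(default_factory=dict)
    missing_rate: Union[float, dict[str, float]] = 0.02
    qual_range: tuple[float, float] = (10.0, 100.0)
    n_alleles: int = 2  # > 2 exercises multi-allelic comparison paths
    # Make founder F2 the allele-wise complement of F1 so the two differ at
    # every site — the idealized divergent-donor scenario used to validate
    # introgression-block recovery.
    divergent_founders: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele_freq must be in (0, 1)")
        if self.n_alleles < 2:
            raise ValueError("need at least 2 alleles per site")
        for name, length in self.chromosomes:
            if self.n_sites > length:
                raise ValueError(
                    f"{name}: {self.n_sites} sites exceed chromosome length {length}"
                )
        for sample, blocks in self.derived.items():
            by_chrom: dict[str, list[Block]] = {}
            for b in blocks:
                by_chrom.setdefault(b.chrom, []).append(b)
            lengths = dict(self.chromosomes)
            for chrom, bs in by_chrom.items():
                bs = sorted(bs, key=lambda b: b.start)
                expected = 1
                for b in bs:
                    if b.start != expected:
                        raise ValueError(
                            f"derived sample {sample}: blocks on {chrom} do not "
                            f"tile the chromosome (gap/overlap at {b.start})"
                        )
                    expected = b.end + 1
                if expected != lengths[chrom] + 1:
                    raise ValueError(
                        f"derived sample {sample}: blocks on {chrom} stop at "
                        f"{expected - 1}, chromosome length is {lengths[chrom]}"
                    )

    def missing_rate_for(self, sample: str) -> float:
        if isinstance(self.missing_rate, dict):
            return self.missing_rate.get(sample, 0.0)
        return float(self.missing_rate)

    @property
    def founder_names(self) -> list[str]:
        return [f"F{i + 1}" for i in range(self.n_founders)]

    @property
    def sample_names(self) -> list[str]:
        return self.founder_names + sorted(self.derived)


@dataclass
class TruthLedger:
    """Ground truth recorded during generation, kept independent of the pipeline.

    ``genotypes[sample]`` is an (n_total_sites, ploidy) int array of allele
    indices *before* missingness; ``forced_missing[sample]`` is the boolean
    mask of calls that were blanked. Site coordinates are parallel arrays.
    """

    chromosomes: ChromosomeSet
    site_chrom: list[str]
    site_pos: np.ndarray
    genotypes: dict[str, np.ndarray]
    forced_missing: dict[str, np.ndarray]
    blocks: dict[str, list[Block]]

    def n_missing(self, sample: str) -> int:
        return int(self.forced_missing[sample].sum())

    def verdicts(self, ref_sample: str, comp_sample: str) -> list[str]:
        """Brute-force per-site verdicts straight from the raw truth.

        Deliberately re-derives SAME/DIFFERENT/MISSING from sorted allele
        lists, not via the comparison engine.
        """
        out = []
        ga, gb = self.genotypes[ref_sample], self.genotypes[comp_sample]
        ma, mb = self.forced_missing[ref_sample], self.forced_missing[comp_sample]
        for i in range(len(self.site_pos)):
            if ma[i] or mb[i]:
                out.append("MISSING")
            elif sorted(ga[i].tolist()) == sorted(gb[i].tolist()):
                out.append("SAME")
            else:
                out.append("DIFFERENT")
        return out

    def expected_bins(
        self, pair: tuple[str, str], metric: Metric, bin_size: int
    ) -> list[BinSeries]:
        """Oracle bin counts for one pair: independent per-site recount."""
        for sample in pair:
            if sample not in self.genotypes:
                raise KeyError(
                    f"unknown sample {sample!r} in ledger; "
                    f"known: {sorted(self.genotypes)}"
                )
        wanted = (
            {"SAME", "DIFFERENT"} if metric is Metric.TOTAL else {metric.value}
        )
        counts = {
            name: np.zeros(n_bins(length, bin_size), dtype=np.int64)
            for name, length in self.chromosomes
        }
        for i, verdict in enumerate(self.verdicts(*pair)):
            if verdict in wanted:
                counts[self.site_chrom[i]][assign_bin(int(self.site_pos[i]), bin_size)] += 1
        return [
            BinSeries(
                chrom=name,
                chrom_length=length,
                bin_size=bin_size,
                counts=counts[name],
                metric=metric,
                pair=pair,
            )
            for name, length in self.chromosomes
        ]

    def expected_block_bins(
        self, sample: str, chrom: str, bin_size: int, donor: str
    ) -> np.ndarray:
        """Boolean mask of bins overlapping the sample's blocks from ``donor``."""
        length = self.chromosomes.length(chrom)
        mask = np.zeros(n_bins(length, bin_size), dtype=bool)
        for b in self.blocks[sample]:
            if b.chrom != chrom or b.donor != donor:
                continue
            mask[assign_bin(b.start, bin_size) : assign_bin(b.end, bin_size) + 1] = True
        return mask

    def to_json(self, path: PathLike) -> None:
        """Persist a compact tabular summary (blocks + missing counts)."""
        doc = {
            "chromosomes": [[n, ln] for n, ln in self.chromosomes],
            "n_sites": len(self.site_pos),
            "samples": sorted(self.genotypes),
            "blocks": {
                s: [[b.chrom, b.start, b.end, b.donor] for b in bs]
                for s, bs in self.blocks.items()
            },
            "forced_missing_per_sample": {
                s: self.n_missing(s) for s in sorted(self.genotypes)
            },
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def three_block_derived(
    spec_chromosomes: Sequence[tuple[str, int]],
    recipient: str,
    donor: str,
    name: str = "D1",
) -> dict[str, list[Block]]:
    """Convenience pedigree: a derived line with 3 donor introgression blocks
    per chromosome (at 1/8-2/8, 4/8-5/8 and 7/8-8/8 of the length), recipient
    background elsewhere."""
    blocks = []
    for chrom, length in spec_chromosomes:
        q = length // 8
        cuts = [
            (1, q, recipient),
            (q + 1, 2 * q, donor),
            (2 * q + 1, 4 * q, recipient),
            (4 * q + 1, 5 * q, donor),
            (5 * q + 1, 7 * q, recipient),
            (7 * q + 1, length, donor),
        ]
        blocks += [Block(chrom, s, e, d) for s, e, d in cuts]
    return {name: blocks}


def simulate(spec: SimulationSpec) -> tuple[VariantDataset, TruthLedger]:
    """Generate a dataset and its truth ledger from a seeded spec."""
    rng = np.random.default_rng(spec.seed)
    samples = spec.sample_names
    founders = spec.founder_names

    site_chrom: list[str] = []
    site_pos_all: list[int] = []
    per_chrom_pos: dict[str, np.ndarray] = {}
    for name, length in spec.chromosomes:
        pos = np.sort(rng.choice(length, size=spec.n_sites, replace=False)) + 1
        per_chrom_pos[name] = pos
        site_chrom += [name] * spec.n_sites
        site_pos_all += pos.tolist()
    total = len(site_pos_all)
    site_pos = np.asarray(site_pos_all, dtype=np.int64)

    # Founder genotypes: two independent allele draws per site (HWE).
    genotypes: dict[str, np.ndarray] = {}
    if spec.n_alleles == 2:
        probs = np.array([1.0 - spec.allele_freq, spec.allele_freq])
    else:
        # allele 0 keeps 1-p; the remaining mass is split evenly over ALTs
        probs = np.concatenate(
            [[1.0 - spec.allele_freq],
             np.full(spec.n_alleles - 1, spec.allele_freq / (spec.n_alleles - 1))]
        )
    for f in founders:
        genotypes[f] = rng.choice(spec.n_alleles, size=(total, 2), p=probs)
    if spec.divergent_founders:
        if spec.n_founders < 2 or spec.n_alleles != 2:
            raise ValueError("divergent_founders needs >= 2 founders and 2 alleles")
        # Fully inbred divergent pair: F1 homozygous at every site, F2 its
        # complement, so the two differ everywhere (hets would complement to
        # the same unordered genotype).
        hom = rng.binomial(1, spec.allele_freq, size=total)
        genotypes[founders[0]] = np.stack([hom, hom], axis=1)
        genotypes[founders[1]] = 1 - genotypes[founders[0]]

    # Derived samples copy the donor founder's genotype inside each block.
    blocks: dict[str, list[Block]] = {f: [] for f in founders}
    site_index = {}
    offset = 0
    for name, _ in spec.chromosomes:
        site_index[name] = (offset, offset + spec.n_sites)
        offset += spec.n_sites
    for sample in sorted(spec.derived):
        g = np.zeros((total, 2), dtype=np.int64)
        for b in spec.derived[sample]:
            lo, hi = site_index[b.chrom]
            pos = per_chrom_pos[b.chrom]
            in_block = (pos >= b.start) & (pos <= b.end)
            g[lo:hi][in_block] = genotypes[b.donor][lo:hi][in_block]
        genotypes[sample] = g
        blocks[sample] = list(spec.derived[sample])

    forced_missing = {
        s: rng.random(total) < spec.missing_rate_for(s) for s in samples
    }
    quals = np.round(rng.uniform(*spec.qual_range, size=total), 1)

    # Assemble sites. ALT alleles listed per site are those actually observed
    # (all indices 1..n_alleles-1 kept so indices stay globally consistent).
    alts = tuple(_REF_ALLELES[1 + i % 3] for i in range(spec.n_alleles - 1))
    sites: list[VariantSite] = []
    for i in range(total):
        calls = {}
        for s in samples:
            if forced_missing[s][i]:
                calls[s] = GenotypeCall((), missing=True)
            else:
                calls[s] = GenotypeCall.from_indices(genotypes[s][i].tolist())
        sites.append(
            VariantSite(
                chrom=site_chrom[i],
                pos=int(site_pos[i]),
                ref="A",
                alts=alts,
                calls=calls,
                qual=float(quals[i]),
            )
        )

    chromosomes = ChromosomeSet(list(spec.chromosomes))
    dataset = VariantDataset(samples=samples, sites=sites, chromosomes=chromosomes)
    ledger = TruthLedger(
        chromosomes=chromosomes,
        site_chrom=site_chrom,
        site_pos=site_pos,
        genotypes=genotypes,
        forced_missing=forced_missing,
        blocks=blocks,
    )
    return dataset, ledger
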