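"""Read and write multi-sample VCF and select representative SNPs per window.

Reading goes through cyvcf2 (htslib), so plain and bgzipped VCF both work.
Writing is a deterministic plain-text VCF 4.2 emitter: the same dataset always
produces the same bytes, which the simulator's reproducibility contract and
the round-trip tests rely on.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Union

from cyvcf2 import VCF

from .model import ChromosomeSet, GenotypeCall, VariantDataset, VariantSite

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_vcf(path: PathLike) -> VariantDataset:
    """Load a VCF 4.x file into a :class:`VariantDataset`.

    Genotypes are taken from the GT FORMAT field; phase separators are
    discarded (``0|1`` == ``0/1``) and any call containing ``.`` — including
    half-calls — is treated as missing. Chromosome lengths come from
    ``##contig`` header lines when present, else the maximum observed position.

    Raises
    ------
    ValueError
        If the file has no samples, a record lacks GT, or sites are not
        strictly sorted by (chrom, pos).
    """
    path = str(path)
    vcf = VCF(path, gts012=False)
    try:
        samples = list(vcf.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample columns")

        header_lengths: dict[str, int] = {}
        try:
            seqlens = vcf.seqlens
        except AttributeError:  # no ##contig length entries in the header
            seqlens = []
        for name, ln in zip(vcf.seqnames, seqlens):
            if ln and ln > 0:
                header_lengths[name] = int(ln)

        sites: list[VariantSite] = []
        chrom_order: list[str] = []
        max_pos: dict[str, int] = {}
        for rec in vcf:
            if rec.FORMAT is None or "GT" not in rec.FORMAT:
                raise ValueError(
                    f"{path}: record {rec.CHROM}:{rec.POS} has no GT FORMAT field; "
                    "genotype comparison requires GT"
                )
            calls: dict[str, GenotypeCall] = {}
            for sample, gt in zip(samples, rec.genotypes):
                # cyvcf2 genotype: [allele_0, ..., allele_{p-1}, phased_flag]
                calls[sample] = GenotypeCall.from_indices(gt[:-1])
            chrom = rec.CHROM
            if chrom not in max_pos:
                chrom_order.append(chrom)
                max_pos[chrom] = 0
            max_pos[chrom] = max(max_pos[chrom], rec.POS)
            sites.append(
                VariantSite(
                    chrom=chrom,
                    pos=rec.POS,
                    ref=rec.REF,
                    alts=tuple(rec.ALT),
                    calls=calls,
                    # htslib hands QUAL back as float32; snap to its printed
                    # precision so round-trips are exact
                    qual=None if rec.QUAL is None else float(f"{rec.QUAL:.6g}"),
                )
            )
    finally:
        vcf.close()

    # Header chromosomes keep header order; chromosomes seen only in the body
    # are appended in order of first appearance.
    entries: list[tuple[str, int]] = []
    seen = set()
    for name in list(header_lengths) + chrom_order:
        if name in seen:
            continue
        if name in header_lengths and name not in max_pos and not sites:
            continue  # empty file: skip header-only contigs below
        seen.add(name)
        entries.append((name, header_lengths.get(name, max_pos.get(name, 1))))
    if sites:
        # Drop header contigs with no sites only if they had no length either.
        entries = [
            (n, ln) for n, ln in entries if n in max_pos or n in header_lengths
        ]
    chromosomes = ChromosomeSet(entries) if entries else ChromosomeSet([("unknown", 1)])

    return VariantDataset(samples=samples, sites=sites, chromosomes=chromosomes)


def list_samples(dataset: VariantDataset) -> list[str]:
    """Sample names in VCF column order."""
    return list(dataset.samples)


def _format_call(call: GenotypeCall) -> str:
    if call.missing:
        return "./."
    return "/".join(str(a) for a in call.alleles)


def _format_qual(qual: Optional[float]) -> str:
    if qual is None:
        return "."
    if float(qual).is_integer():
        return str(int(qual))
    return f"{qual:g}"


def write_vcf(dataset: VariantDataset, path: PathLike) -> None:
    """Write the dataset as plain VCF 4.2 with ##contig header lines.

    Output is byte-deterministic for a given dataset.
    """
    lines = ["##fileformat=VCFv4.2"]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for name, length in dataset.chromosomes:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(dataset.samples)
    )
    for site in dataset.sites:
        alt = ",".join(site.alts) if site.alts else "."
        gts = "\t".join(_format_call(site.calls[s]) for s in dataset.samples)
        lines.append(
            f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{alt}\t"
            f"{_format_qual(site.qual)}\t.\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def subsample(
    dataset: VariantDataset, min_qual: float = 0.0, window: int = 500_000
) -> VariantDataset:
    """Quality-filter sites and keep one representative SNP per genomic window.

    Windows are fixed, non-overlapping, 1-based inclusive intervals
    [k*window + 1, (k+1)*window]. Within each window the retained site is the
    qualifying site closest to the window midpoint; ties break toward the
    lower coordinate. Sites with ``QUAL`` below ``min_qual`` are dropped, as
    are sites lacking QUAL entirely when ``min_qual > 0``.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if min_qual < 0:
        raise ValueError(f"min_qual must be >= 0, got {min_qual}")

    kept: list[VariantSite] = []
    # (chrom, window index) -> best (distance to midpoint, pos, site)
    best: dict[tuple[str, int], tuple[float, int, VariantSite]] = {}
    for site in dataset.sites:
        if min_qual > 0 and (site.qual is None or site.qual < min_qual):
            continue
        k = (site.pos - 1) // window
        midpoint = k * window + (window + 1) / 2.0
        key = (site.chrom, k)
        cand = (abs(site.pos - midpoint), site.pos, site)
        if key not in best or cand < best[key]:
            best[key] = cand

    order = {name: i for i, (name, _) in enumerate(dataset.chromosomes.entries)}
    kept = [site for _, _, site in best.values()]
    kept.sort(key=lambda s: (order[s.chrom], s.pos))

    if not kept:
        warnings.warn(
            "subsample removed every site (min_qual=%s, window=%s)"
            % (min_qual, window),
            stacklevel=2,
        )
    log.info(
        "subsample: kept %d of %d sites (min_qual=%s, window=%d bp)",
        len(kept),
        dataset.n_sites,
        min_qual,
        window,
    )
    return VariantDataset(
        samples=list(dataset.samples), sites=kept, chromosomes=dataset.chromosomes
    )
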