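"""Classify every site of a (reference, comparison) accession pair.

The verdict at a site is:

* ``MISSING`` — either call is missing;
* ``SAME``    — the two unordered allele multisets are equal;
* ``DIFFERENT`` — otherwise (heterozygote vs homozygote counts as different,
  as does one heterozygote vs another sharing a single allele).

SAME/DIFFERENT/MISSING therefore partition the sites of any pair. Exact
multiset equality is the strictest reading of "same as the reference"; users
interpreting heterozygote-rich data should keep that in mind (a 0/1 call
against a 0/0 reference is DIFFERENT, not partially same).
"""

from __future__ import annotations

import logging

from .model import (
    GenotypeCall,
    PairComparison,
    SiteClassification,
    VariantDataset,
    Verdict,
)

log = logging.getLogger(__name__)


def classify_site(
    ref_call: GenotypeCall, comp_call: GenotypeCall, site_label: str = ""
) -> Verdict:
    """Verdict for one pair of calls at a single site.

    Raises
    ------
    ValueError
        If both calls are present but have different ploidy.
    """
    if ref_call.missing or comp_call.missing:
        return Verdict.MISSING
    if len(ref_call.alleles) != len(comp_call.alleles):
        where = f" at {site_label}" if site_label else ""
        raise ValueError(
            f"ploidy mismatch{where}: {len(ref_call.alleles)} vs "
            f"{len(comp_call.alleles)} alleles"
        )
    # GenotypeCall stores alleles sorted, so tuple equality is multiset equality.
    return Verdict.SAME if ref_call.alleles == comp_call.alleles else Verdict.DIFFERENT


def compare_pair(
    dataset: VariantDataset, ref_sample: str, comp_sample: str
) -> PairComparison:
    """Classify every site of the dataset for one accession pair.

    Self-comparison is permitted (every called site is SAME) but logged as a
    warning, since it is usually a user mistake.
    """
    dataset.require_sample(ref_sample)
    dataset.require_sample(comp_sample)
    if ref_sample == comp_sample:
        log.warning(
            "comparing sample %r against itself: all called sites will be SAME",
            ref_sample,
        )
    classifications = [
        SiteClassification(
            chrom=site.chrom,
            pos=site.pos,
            verdict=classify_site(
                site.calls[ref_sample],
                site.calls[comp_sample],
                site_label=f"{site.chrom}:{site.pos}",
            ),
        )
        for site in dataset.sites
    ]
    return PairComparison(
        ref_sample=ref_sample,
        comp_sample=comp_sample,
        classifications=classifications,
    )
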