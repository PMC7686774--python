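"""Identity-by-state (IBS) similarity between accessions.

The score between two diploid accessions is the mean, over sites where both
are called, of s/2 where s is the number of alleles the two genotype
multisets share (0, 1 or 2). Identical genotypes everywhere give 1.0;
disjoint homozygotes everywhere give 0.0. This emulates the IBS statistic of
standard SNP-panel toolkits (it is a documented definition, not a
bit-compatible port of any particular package). Typical use: flagging
duplicate or mislabeled accessions — near-identical lines score close to 1,
unrelated lines score near the panel's background sharing level.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import GenotypeCall, VariantDataset

PathLike = Union[str, Path]


def _shared_alleles(a: GenotypeCall, b: GenotypeCall) -> int:
    """Multiset intersection size of two allele multisets."""
    ca, cb = Counter(a.alleles), Counter(b.alleles)
    return sum((ca & cb).values())


def ibs_pair(dataset: VariantDataset, sample_a: str, sample_b: str) -> float:
    """Mean fraction of shared alleles across sites where both samples are called.

    Raises
    ------
    ValueError
        If no site has both samples called (the score is undefined, not 0).
    """
    dataset.require_sample(sample_a)
    dataset.require_sample(sample_b)
    shared = 0.0
    n = 0
    for site in dataset.sites:
        ca, cb = site.calls[sample_a], site.calls[sample_b]
        if ca.missing or cb.missing:
            continue
        ploidy = max(len(ca.alleles), len(cb.alleles))
        shared += _shared_alleles(ca, cb) / ploidy
        n += 1
    if n == 0:
        raise ValueError(
            f"IBS undefined for ({sample_a}, {sample_b}): no site where both are called"
        )
    return shared / n


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise IBS matrix with unit diagonal."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("similarity values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)

    def to_tsv(self, path: Optional[PathLike] = None) -> str:
        text = self.to_frame().to_csv(sep="\t", float_format="%.6f")
        if path is not None:
            Path(path).write_text(text)
        return text

    def score(self, a: str, b: str) -> float:
        return float(self.values[self.samples.index(a), self.samples.index(b)])


def similarity_matrix(
    dataset: VariantDataset, samples: Optional[Sequence[str]] = None
) -> SimilarityMatrix:
    """Pairwise IBS for the given samples (default: all samples)."""
    names = list(samples) if samples is not None else list(dataset.samples)
    if len(names) < 2:
        raise ValueError("similarity matrix needs at least 2 samples")
    for name in names:
        dataset.require_sample(name)
    n = len(names)
    values = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                score = ibs_pair(dataset, names[i], names[j])
            except ValueError as exc:
                raise ValueError(
                    f"similarity failed for pair ({names[i]}, {names[j]}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = score
    return SimilarityMatrix(samples=names, values=values)
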