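"""Shared fixtures: hand-written VCF text and small simulated datasets."""

from __future__ import annotations

import pytest

from snpview.simulate import Block, SimulationSpec, simulate, three_block_derived

# Hand-written VCF exercising phasing, missing calls, half-calls and QUAL.
HAND_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=Chr1,length=1000000>
##contig=<ID=Chr2,length=800000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB
Chr1\t100\t.\tA\tT\t50\t.\t.\tGT\t0/1\t0|1
Chr1\t450\t.\tG\tC\t10\t.\t.\tGT\t0/0\t1/1
Chr1\t900000\t.\tT\tA\t40\t.\t.\tGT\t./.\t0/.
Chr2\t5\t.\tC\tG,T\t99.5\t.\t.\tGT\t1/2\t2|1
"""


@pytest.fixture
def hand_vcf(tmp_path):
    path = tmp_path / "hand.vcf"
    path.write_text(HAND_VCF)
    return path


@pytest.fixture
def small_sim():
    """Two divergent founders plus a 3-block introgression line, no missing."""
    chroms = [("Chr1", 8_000_000), ("Chr2", 8_000_000)]
    spec = SimulationSpec(
        seed=11,
        chromosomes=chroms,
        n_sites=400,
        n_founders=2,
        derived=three_block_derived(chroms, recipient="F1", donor="F2"),
        divergent_founders=True,
        missing_rate=0.0,
    )
    return simulate(spec)


@pytest.fixture
def noisy_sim():
    """Four founders at intermediate frequency with missing calls."""
    chroms = [("Chr1", 4_000_000), ("Chr2", 2_000_000)]
    spec = SimulationSpec(
        seed=23,
        chromosomes=chroms,
        n_sites=300,
        n_founders=4,
        allele_freq=0.3,
        derived={
            "D1": [
                Block("Chr1", 1, 2_000_000, "F1"),
                Block("Chr1", 2_000_001, 4_000_000, "F2"),
                Block("Chr2", 1, 2_000_000, "F3"),
            ]
        },
        missing_rate=0.05,
    )
    return simulate(spec)
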