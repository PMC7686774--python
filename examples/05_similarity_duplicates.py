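"""Flag duplicate accessions with the identity-by-state matrix.

A germplasm panel sometimes carries the same line under two names. IBS
close to 1.0 between two differently named accessions is the signature;
unrelated lines sit near the panel's background sharing level.
"""

from snpview import similarity_matrix
from snpview.simulate import Block, SimulationSpec, simulate

spec = SimulationSpec(
    seed=21, chromosomes=[("Chr1", 2_000_000)], n_sites=2000,
    n_founders=3, allele_freq=0.4,
    # "Mystery" is secretly founder F2 under another name
    derived={"Mystery": [Block("Chr1", 1, 2_000_000, "F2")]},
    missing_rate=0.01,
)
dataset, _ = simulate(spec)

matrix = similarity_matrix(dataset)
print(matrix.to_tsv(), end="")
print(f"\nIBS(F2, Mystery) = {matrix.score('F2', 'Mystery'):.3f} "
      "-> same accession under two names")
print(f"IBS(F1, F3)      = {matrix.score('F1', 'F3'):.3f} "
      "-> unrelated lines share alleles only by chance")
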