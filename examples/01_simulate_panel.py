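"""Generate a synthetic SNP panel with known introgression structure.

Two fully divergent inbred founders (F1, F2) and a derived line D1 that
carries three F2 introgression blocks per chromosome on an F1 background.
The truth ledger records exactly which segment came from which donor.
"""

from snpview import write_vcf
from snpview.simulate import SimulationSpec, simulate, three_block_derived

chroms = [("Chr1", 8_000_000), ("Chr2", 8_000_000)]
spec = SimulationSpec(
    seed=42,
    chromosomes=chroms,
    n_sites=1600,
    n_founders=2,
    derived=three_block_derived(chroms, recipient="F1", donor="F2"),
    divergent_founders=True,
    missing_rate=0.02,
)
dataset, truth = simulate(spec)
write_vcf(dataset, "panel.vcf")
truth.to_json("panel_truth.json")

print(f"samples: {dataset.samples}")
print(f"sites:   {dataset.n_sites} across {len(dataset.chromosomes)} chromosomes")
for block in truth.blocks["D1"][:6]:
    print(f"  D1 {block.chrom}:{block.start}-{block.end} from {block.donor}")
print("Each line above is a ground-truth ancestry segment of the derived "
      "line; the VCF and ledger were written to panel.vcf / panel_truth.json.")
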