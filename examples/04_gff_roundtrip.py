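"""Export binned tracks to GFF3 and read them back unchanged.

The GFF3 file is the portable description of a figure: one feature per bin,
raw count in the score column. A figure rendered from the GFF3 is
byte-identical to one rendered straight from the VCF.
"""

import numpy as np

from snpview import Metric, bin_counts, compare_pair, read_gff, write_gff
from snpview.simulate import SimulationSpec, simulate

spec = SimulationSpec(
    seed=12, chromosomes=[("Chr1", 4_000_000)], n_sites=600,
    n_founders=2, missing_rate=0.03,
)
dataset, _ = simulate(spec)

pair = compare_pair(dataset, "F1", "F2")
tracks = bin_counts(pair, Metric.DIFFERENT, 500_000, dataset.chromosomes)
write_gff(tracks, "track.gff3")

recovered = read_gff("track.gff3")
identical = all(
    np.array_equal(a.counts, b.counts) and a.pair == b.pair
    for a, b in zip(tracks, recovered)
)
print(f"wrote track.gff3 with {tracks[0].n_bins} features "
      f"(pair {tracks[0].pair}, metric {tracks[0].metric.value})")
print(f"read back: counts and metadata identical -> {identical}")
print("Because zero-count bins are written too, the file alone fully "
      "reconstructs the binned track.")
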