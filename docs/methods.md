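# Methods

## Site classification

All comparisons are within one dataset: a multi-sample VCF mapped to a
single reference genome assembly (the *reference accession* chosen for a
comparison is a sample column, not the assembly). A genotype call is the
unordered multiset of its allele indices; phase separators are discarded
because every downstream statistic is allele-content based. Any call
containing `.` — including half-calls like `0/.` — is treated as missing,
the conservative reading that avoids inventing semantics for partially
observed genotypes.

A (reference, comparison) pair's verdict at a site is MISSING if either
call is missing, SAME on exact multiset equality, DIFFERENT otherwise.
Exact equality is the strictest defensible rule and the only one that makes
SAME/DIFFERENT/MISSING a true partition; its user-visible consequence is
that a heterozygote never counts as "same" as a homozygote, so
heterozygote-rich material shows inflated difference tracks relative to a
shares-an-allele rule. Multi-allelic sites are compared on their allele
indices as-is; ploidy mismatches between two present calls are an error
rather than silently resolved.

## Binning and display scaling

Bin *k* of size *B* covers the 1-based inclusive interval
[*kB*+1, (*k*+1)*B*], the final bin truncated at the chromosome length;
this matches VCF/GFF3 coordinate conventions. The default *B* = 500 kb
suits array-density SNP data on ~50 Mb plant chromosomes (roughly tens of
sites per bin); denser data tolerates smaller bins until a bin's pixel
height falls below 1, at which point the layout warns. TOTAL counts sites
where both accessions are called — the sites actually usable in the
comparison — so per-bin SAME + DIFFERENT = TOTAL always holds and MISSING
is never drawn.

Histogram and heatmap values are (count − m)/(M − m) clamped to [0, 1].
m and M default to the minimum and maximum over *all bins of all
chromosomes of that one track* (genome-wide, per track): tracks with
different metrics or pairs are not commensurable, so no cross-track
normalization is attempted. A flat track (M = m) scales to all zeros.
User-supplied bounds clamp rather than error, which lets a fixed maximum
(e.g. 30) saturate high-difference regions deliberately. Haplotype
presence uses the inclusive rule count ≥ threshold, making presence sets
monotone non-increasing in the threshold.

## Chromosome lengths, GFF3 dialect

Lengths come from `##contig` headers when present (authoritative), else the
maximum observed position. The GFF3 export writes one `comparison_bin`
feature per bin — zero-count bins included, so the file alone reconstructs
the figure — with the raw count in the score column and
`ref/sample/metric/bin` attributes. On reading, the bin size is inferred as
the modal feature span (only final bins can be truncated, so ties break
toward the larger span); the dialect is stable and documented but not
claimed bit-identical to any other tool's GFF output.

## Subsampling

`subsample` drops sites below a QUAL floor (sites without QUAL are dropped
only when a floor is actually set) and keeps at most one site per fixed,
non-overlapping window. The representative is the qualifying site nearest
the window midpoint, ties toward the lower coordinate: of the defensible
rules (first, highest-quality, most central), the midpoint rule yields the
most spatially even retained set, which is what a binned display wants.
The operation is idempotent at a fixed window size.

## Identity-by-state

IBS(a, b) is the mean over co-called sites of s/2 with s the shared-allele
multiset size. This emulates the IBS statistic of standard SNP toolkits as
a documented definition, not a bit-compatible port. With zero comparable
sites the score is undefined and raised as an error, never reported as 0.
For two independent Hardy–Weinberg diploids at allele frequency p = 0.5,
direct enumeration of the 3×3 genotype table gives E[s/2] = 5/8 (the
het×het cell shares both alleles), which the Monte-Carlo test reproduces
within 3 standard errors at 10⁵ sites.

## Rendering

The figure is a pure function of (scaled tracks, view spec): elements are
emitted in a fixed order with fixed 3-decimal coordinate formatting, so
identical inputs give byte-identical SVG. Backbones are vertical, at a
uniform bp-to-pixel scale (600 px for the longest chromosome); each track
occupies a 40 px band on its chosen side, histogram bars grow horizontally
from the backbone, zero-length bars are suppressed, and haplotype cells are
drawn only where present. Ruler labels are in Mb with one decimal, default
interval 5 Mb — typical for plant genomes. The heatmap ramp defaults to
white → track color. Centromere-style annotations are an optional overlay
from a 3-column BED file (0-based half-open, converted to 1-based
internally). PNG output goes through a built-in rasterizer (lxml + Pillow)
that draws exactly the rect/line/text subset the SVG writer emits; text is
rendered with Pillow's default font, so PNG typography is approximate while
geometry is exact.

## Synthetic panels and the truth ledger

The generator emulates SNP-array genotype panels for a selfing diploid
crop: founders drawn independently under Hardy–Weinberg at a common allele
frequency, derived lines assembled by copying founder genotypes block-wise
(the mosaic left by introgression breeding), uniform site placement,
missingness injected per sample, Phred-like QUAL ~ Uniform(10, 100).
Defaults — 4 chromosomes × 50 Mb, 2,500 sites per chromosome, 4 founders,
allele frequency 0.3, 2% missing — give array-like density (one site per
20 kb) on plant-scale chromosomes. A `divergent_founders` switch makes the
first two founders homozygous complements (fully inbred, maximally
divergent parents), the idealized scenario in which block recovery can be
exact: heterozygous founders would complement to the same unordered
genotype, so homozygosity is required, not incidental. What the generator
deliberately does **not** model: linkage disequilibrium, allele-frequency
spectra of real panels, genotyping-error structure, clustered marker
placement. Tests passing on these panels therefore validate the
*bookkeeping* — classification, binning, scaling, serialization, drawing —
not robustness to real-data artifacts.

The truth ledger stores the raw genotype matrices, forced-missing masks and
block intervals recorded at generation time, and recounts per-bin verdicts
with its own sorted-allele-list comparison — a code path independent of the
comparison engine — so pipeline-vs-oracle tests are genuine dual routes.

## Problem sizes and numerical choices

Tests and the acceptance script use panels of 120–1,600 sites on 2–8 Mb
chromosomes (50 panels for the partition sweep) and a single 10⁵-site
chromosome for the Monte-Carlo IBS check; these sizes exercise every code
path with multi-bin, multi-chromosome structure while keeping any single
check in seconds. Block-recovery scenarios use 8 Mb chromosomes so the
block boundaries (at 1 Mb multiples) align with the 500 kb bin grid; a
deliberately misaligned-boundary case is tested separately at site
resolution. Color interpolation rounds half to even per channel; the SVG
audit tolerance is one pixel of bar width expressed in counts,
(M − m)/40.

## Limitations

- No variant calling, liftover, imputation, phasing inference or LD-aware
  simulation; INFO fields beyond QUAL are ignored.
- The exact-match SAME rule is one defensible choice; results on
  outcrossing, heterozygous material should be interpreted with the
  het-vs-hom behavior in mind.
- Rendering aims at structural, not pixel, parity with browser-based
  genome viewers; interactive features (zoom, drawing, pop-ups) are out of
  scope, with `bin_report` providing the pop-up's content programmatically.
- The rasterizer covers only this package's SVG subset; arbitrary SVG is
  rejected rather than mis-drawn.
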