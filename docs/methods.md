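# Methods

## The analysis model

`chipcomp` implements a probe-based comparative ChIP-seq analysis for a
single small replicon. The unit of quantitation is a fixed-width genomic
probe (default 50 bp), tiled gaplessly over `[0, L)`; the final probe is
truncated at the genome end rather than dropped, so the tiling is exact.
All internal coordinates are 0-based half-open; GFF3 and SAM (1-based
inclusive) are converted only at the format boundary, BED passes through
unchanged.

**Counting.** A uniquely mapped read increments every probe its interval
overlaps by at least one base. With 300–500 bp fragments on 50 bp probes a
read touches ~7–11 consecutive probes, so probe values are spatially
correlated and probe percents sum to more than 100 — this is intentional:
the normalization denominator is the sample's *read* total, not the
contribution total. Uniqueness is taken from the alignment record
(secondary/supplementary flag, MAPQ 0, or an NH/X0 multi-hit tag marks a
read non-unique); for BED input every interval is treated as unique. On a
circular genome, a fragment spanning the origin junction is represented as
two linear sub-intervals sharing one read name; counting is then purely
linear, and read totals count distinct names.

**Peak calling.** Per sample, over all percent-normalized probe values,
`cutoff = mean + 2·SD` with the n−1 (sample) SD. At genome scale
(~8×10⁴ probes) the n vs n−1 choice is numerically irrelevant (<10⁻⁴
relative); it matters only in toy examples. Candidates are probes with
percent *strictly* above the cutoff — ties at the cutoff are background —
and maximal runs of consecutive candidate probes merge into peak intervals.
No input subtraction, local background, or FDR control is applied; the
cutoff is the whole model. Note the cutoff is computed on the full track
including enriched probes, so heavy enrichment inflates the SD and makes
the caller conservative; that behavior is inherent to the method, not
corrected for.

**Annotation.** A candidate probe is assigned to a gene when the probe
center lies within −500/+100 of the gene's TSS, oriented by strand
(+ strand: `[tss−500, tss+100]`; − strand mirrored), bounds inclusive at
both ends. The TSS is the strand-appropriate extremity of the annotated
gene body; operon-internal genes are treated like any other. Probe center
for even widths is the left of the two middle bases, `⌊(start+end−1)/2⌋` —
deterministic, at the cost of exact mirror symmetry only for odd widths
(the even-width convention shifts reflected centers by 1 bp, a ≤1-probe
boundary effect). A probe may be annotated to two genes only when they are
on opposite strands (a divergent promoter pair); if several same-strand
genes' windows contain the center — possible in dense toy genomes — the
nearest TSS on that strand wins (ties broken by TSS coordinate, then gene
id). Windows clip at the ends of a linear genome and wrap on a circular
one. No match ⇒ `NO ANNO`. Point-in-window queries go through an interval
tree; the test suite checks them against a brute-force all-pairs oracle.

**Differential occupancy.** Two tracks on an identical probe grid are
compared as `log2((p_alt + ε)/(p_ref + ε))`, computed as
`log2(p_alt+ε) − log2(p_ref+ε)` so that swapping conditions negates every
value bit-exactly. ε defaults to the percent equivalent of one read in the
shallower sample, `100/min(N_ref, N_alt)` — a scale-aware guard for
zero-coverage probes that also damps ratios at near-empty probes;
|log₂ ratio| is non-increasing in ε. Percent normalization is the only
depth correction between samples. Target ranking restricts to probes that
are candidates in at least one condition and sorts by |log₂ ratio|
descending, ties broken by genome coordinate (stable sort). No significance
testing is attached to the ratios: the design has one comparative run per
condition, so magnitudes are the result.

## Synthetic data: what it emulates, what it does not

The generator models the study conditions the pipeline is meant for: a
200 kb circular genome, 50 non-overlapping genes of 600–1500 bp placed with
uniformly random intergenic spacing on both strands, 10⁵ IP reads per
condition, fragment lengths uniform on 300–500 bp (the sonication shear
target), and planted enrichment at 3 loci of half-width 500 bp at fold 10 —
two centered in real promoter windows (one per strand) and one "origin-like"
locus in the largest intergenic gap, enriched in only one condition. Those
defaults are the package's canonical demonstration; the sizes keep a full
two-condition run around a second on one CPU.

Reads are drawn by fragment *midpoint* from a mixture: uniform background
of mass `L` plus `(fold−1)·width` extra mass per enriched window, so the
expected midpoint density inside a window is exactly `fold ×` background.
Midpoints (not 5′ ends) carry the enrichment because ChIP signal is
symmetric about the bound site. Consequently enriched *fragments* cover the
midpoint window padded by up to half the maximum fragment length on each
side; the truth table records both the midpoint window and this enriched
footprint, and peak-precision checks score called bases against the
footprint — coverage spill beyond the midpoint window is real signal, not a
false call. One RNG stream per (seed, condition) keeps each condition's
reads reproducible independently of evaluation order; the full output is a
pure function of (config, seed).

Deliberately not modeled: sequencing error, GC or mappability bias,
input-chromatin structure (background is uniform — the simplest null under
which mean+2·SD is meaningful), replicates, and multi-replicon genomes.
Passing tests on this generator demonstrate the pipeline's arithmetic and
its recovery of strong planted signal (fold ≥ 8 at ≥10⁵ reads); they say
nothing about performance on noisy real backgrounds, weak enrichment, or
biased coverage.

## Assay math

The qPCR standard curve is ordinary least squares of Ct on log₁₀ quantity
over serially diluted input (≥3 distinct dilutions required; quantity unit
= the undiluted input aliquot). An IP sample's quantity is interpolated as
`10^((Ct − intercept)/slope)`; because the input aliquot is a fraction
(default 0.10) of the total chromatin, `% input = 100 · q_ip ·
input_fraction`. The fraction is a parameter, not a constant, since
published percent-input figures do not always state whether the aliquot
correction was applied. Amplification efficiency `10^(−1/slope) − 1` is
reported as a diagnostic but never used to re-correct quantities — the
curve interpolation already embeds it. Replicates aggregate as mean ±
SD/√n. Miller units are the exact formula `U = (A420·1000)/(A660·t·v)`
with all-positive inputs enforced.

## Numerical and design choices

- **Overlap rule** (any-overlap ≥1 bp, not midpoint containment): declared
  explicitly; with planted fold ≥ 8 the downstream results are insensitive
  to the choice.
- **Strict inequality at the cutoff**; an all-equal track has SD 0 and
  zero candidates.
- **Final partial probe retained**, preserving the tiling invariant.
- **Probe tables serialize percents at 17 significant digits**, so
  write→read round trips are bit-exact.
- **Output determinism**: no timestamps in file headers; identical
  (config, seed) reproduces every output byte-for-byte. Each output's
  header records the parameters needed to re-run that stage.
- **Degenerate inputs**: zero total reads yields an all-zero percent track
  with a logged warning (not an error); an empty read set is valid; fewer
  than two probes, non-positive ε, or a non-negative curve slope are hard
  errors.

## Known limitations

- Single replicon per analysis; multi-chromosome/plasmid data must be run
  per replicon.
- The mean+2·SD cutoff has no error control; candidate counts scale with
  track composition, and comparing candidate sets across samples with very
  different enrichment mass can be misleading (the log₂ ranking partially
  compensates).
- Uniqueness for BED input cannot be verified and is assumed.
- The annotation cap (≤1 gene per strand, ≤2 total) discards additional
  same-strand matches in gene-dense regions.
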