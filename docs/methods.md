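# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of the `regengrn` pipeline.

## Study design

Samples follow a five-point optic-nerve-regeneration time course —
0 (uninjured), 2, 4, 7 and 12 days post-injury (dpi) — with three
biological replicates per timepoint. Every comparison is "timepoint t
versus 0 dpi". All genomic coordinates are 0-based half-open; GFF3 input
is converted on read and the TSS of a minus-strand gene is `end − 1`.

## Expression and accessibility testing

Counts (transcript × sample, or peaklet × sample) are modeled as negative
binomial with one mean per timepoint; with a log link and a saturated
time factor the group MLE is the group mean, so no iterative GLM fit is
needed. Features with total count < 10 are excluded before testing.

**Dispersion.** A per-feature pooled method-of-moments estimate
(`Var = μ + αμ²` across groups) is unusably noisy at 2–3 replicates per
group and makes the asymptotic tests anticonservative. We therefore fit a
single common dispersion by maximizing the Cox–Reid-adjusted profile
likelihood (the adjustment subtracts `½ Σ_t log(n_t μ_t/(1+αμ_t))`, the
log-determinant of the mean-parameter information, removing most plug-in
bias) and shrink each feature's moment estimate toward it:

    α_i = (d·α_mom,i + d₀·α_common) / (d + d₀),  d = S − T (residual df), d₀ = 40

The strong prior weight reflects the small residual df (10 in the default
design); with it the null likelihood-ratio p-values are near-uniform
(Kolmogorov–Smirnov check in the test suite) and the empirical FDR of the
BH-thresholded calls sits close to the nominal 5% level.

**Tests.** The Wald z for contrast t vs 0 uses the delta-method variance
of the log ratio of (mean + 0.5)-offset group means,
`Var ≈ (1/(μ_t+½)+α)/n_t + (1/(μ_0+½)+α)/n_0`; the offset keeps
zero-count groups finite and testable. The LRT compares the per-timepoint
model against a single-mean null on χ²(T−1). Benjamini–Hochberg runs per
test family (per contrast across features; across features for the LRT).
Differential-accessibility direction is the sign of the log2 fold-change
at the significant contrast ("open" > 0, "closed" < 0).

## Normalization and clustering

TPM is recomputed from counts and effective lengths per sample (column
sums are exactly 10⁶; they are *not* preserved under row subsetting — the
suite checks this, and subsets must renormalize if per-subset TPM is
wanted). Profiles are `log2(TPM+1)` standardized per transcript across
all samples with the sample (n−1) SD; zero-variance rows are flagged and
excluded from clustering. K-means is plain Lloyd iteration: each restart
(default 10) seeds centroids from K distinct data rows, iterates to
assignment stability or 300 iterations, repairs an empty cluster by
reseeding it with the point farthest from its centroid, and the restart
with the lowest within-cluster sum of squares wins; within-SS is asserted
non-increasing per iteration. Everything is deterministic given the seed.

## Peaklets and annotation

Summits with p ≥ 10⁻¹⁰ are dropped; each retained summit yields a
`[s−250, s+250)` window clipped to the chromosome; overlapping windows
are kept distinct (fixed-window counting, no merging); ids follow
(chrom, pos) sort order. Read counting is fully vectorized per chromosome
with two sorted-array rank queries (`count(start < peaklet_end) −
count(end ≤ peaklet_start)`), which is exact for ≥ 1 bp overlap.

Annotation measures |peaklet center − TSS| (the center-based rule),
unstranded, ties broken by lexicographic gene id. Proximal ≤ 1 kb; distal
in (1 kb, 100 kb); otherwise unassigned. A peaklet whose maximum overlap
with any single exon exceeds 50 bp is excluded from the proximal/distal
assignment (reason recorded) but still gets a genic class so the genomic
distribution can report exonic peaklets; genic precedence is
5′UTR > exon > intron > intergenic on any 1 bp overlap. Both windows and
the exon-overlap bound are configuration, not constants in code paths.

## Motif scanning and enrichment

PFMs become log2-odds PWMs with background-proportional pseudocounts:
`log2(((c_bj + p·bg_b)/(Σc_j + p)) / bg_b)`, default pseudocount 1.
Background frequencies are estimated from the peaklet sequence set (the
same universe the enrichment test uses), not the whole genome. Both
strands are scanned; windows containing N score −∞; a hit requires a
score ≥ 0.8 × the motif's maximum achievable score. The fraction-of-max
threshold (rather than a p-value-calibrated one) keeps the scanner
self-contained; it is exposed in configuration. Enrichment is a one-sided
Fisher exact test on hit/no-hit × foreground/background; a background
that is a superset of the foreground is treated as the sampling universe
(hypergeometric upper tail). BH runs across the motifs tested together.
Co-occurrence counts peaklets hit by both motifs; the fraction divides by
the union (Jaccard) by default, by the smaller set via configuration.

## TF selection and target inference

A catalog TF is retained when ≥ 1 of its transcripts passes the LRT at
the configured FDR; its cluster is that of its most significant
transcript; catalog entries without a usable motif are reported
separately and excluded from motif-based stages. Proximity ranking takes
the minimum |TSS − DA-peaklet center| per TF (infinite when its
chromosome has none), flagging TFs within 100 kb. A gene is a putative
target of a TF when (a) one of its proximal/distal peaklets contains a
hit of the TF's motif and (b) the gene is differentially expressed in a
temporally compatible cluster — by default the same cluster; a
same-or-adjacent option exists because regulators plausibly act into the
following expression wave. Every edge records its (peaklet, location,
offset, strand) evidence, and the suite re-scans evidence peaklets to
verify it. Gene-set summaries are plain hypergeometric upper tails over a
user-supplied universe (no ontology download).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

- **Genome/annotation** — uniform-ACGT chromosomes; non-overlapping,
  evenly slotted 2 kb genes with alternating strands, two exons and a
  strand-aware 100 bp 5′UTR; one transcript per gene.
- **Expression** — seven archetype profiles over the five timepoints
  (early/mid/late up, early/mid/late down, down-then-late-up), scaled by
  the planted effect (default 2 log2 units = 4-fold); 35% of genes carry
  an archetype, the rest are flat; counts are NB around
  lognormal baselines (median 200) with dispersion 0.1.
- **Accessibility** — one proximal summit 300–700 bp upstream of each TSS
  and 1–3 distal summits 2.4–4.0 kb from it (inside the study's 1–100 kb
  distal window but clear of the 2 kb gene body, so planted peaklets are
  never exon-excluded); NB counts around mean 50; 5% of peaklets are
  differentially accessible — opening at 2 dpi or closing at 12 dpi,
  mirroring the early/late concentration of accessibility change — and a
  designated cluster-1 regulator is flanked by three differentially open
  peaklets at 2 dpi (one promoter-proximal, two distal), emulating an
  immediate-early gene; sub-threshold decoy summits exercise the p-value
  retention rule.
- **Motifs** — one dominant base (count 85 of 100) per column, lengths
  8–12; one motif per temporal cluster is the cluster regulator's. Motif
  *consensus* sequences are written verbatim into the genome inside
  peaklets of cluster-matched genes at the plant rate (default 0.9);
  planting avoids overwriting earlier sites and reuses a site shared by
  overlapping peaklets, so the truth manifest always matches the genome.
  Consensus (not PFM-sampled) instances are planted because the 0.8-of-max
  scanning threshold on these sharp motifs admits essentially exact
  matches only.
- **Reads** — fixed-length (100 bp) intervals jittered ±150 bp around
  summit centers, so drawn counts equal overlap counts except for
  double-counting by rare overlapping peaklets. No fragment-length, Tn5,
  GC or batch structure is simulated.

Ground truth (cluster per gene, DA peaklets with direction, planted hits,
TF→target edges) is written as a JSON manifest. All outputs are a pure
function of (config, seed), via independent named substreams.

What passing tests on this generator do **not** show: robustness to
library-size imbalance, batch effects, dispersion trends in the mean,
overdispersed motif backgrounds (real genomes are not i.i.d. uniform),
isoform-level ambiguity, or annotation errors — real data exercise all of
these.

## Problem sizes and runtime

Cluster-recovery checks run at 2,000 transcripts; calibration and
accessibility-recovery checks use 20 replicates of 500 features / 300
peaklets; the full end-to-end pipeline runs at 120–300 genes. These sizes
give stable estimates of the recovery and calibration quantities while
keeping the whole suite and the acceptance script to a couple of minutes
on one CPU.

## Known limitations

- The NB Wald/LRT is a deliberate simplification of bootstrap-based
  transcript-level inference; downstream logic consumes only per-contrast
  p/q values and fold-changes.
- The common-dispersion shrinkage assumes dispersions are exchangeable
  across features; a strong mean–dispersion trend would call for a
  trended fit.
- The scanner's fraction-of-max threshold is not calibrated to a match
  p-value; sharply informative motifs are found near-exactly, degenerate
  motifs more promiscuously.
- Proximal/distal assignment uses the center-based distance rule; the
  alternative "any overlap with a 1 kb TSS window" reading changes edge
  cases only but is not implemented as a switch for genic classes.
- The error surfaced for a missing genome names the first stage that
  needs it (peaklet construction requires chromosome sizes), not the
  motif-scanning stage.
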