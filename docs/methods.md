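# Methods

## Coordinates and formats

All coordinates are 0-based half-open internally. BED, BEDPE-like loop
tables and matrix triplets are native; SEG and GTF-lite gene tables (1-based
inclusive) are converted exactly once at read time. Chromosome names are
matched as exact strings — no `chr` aliasing — so naming mismatches surface
as missing overlaps instead of being silently patched. Promoter windows are
`2*flank + 1` bases centered on the strand-aware TSS base (default flank
1 kb), clipped at the chromosome origin.

## Loop annotation and union sets

An anchor is labeled *promoter* when it overlaps any promoter window,
otherwise *enhancer* when it overlaps any H3K27ac peak, otherwise *neither*;
the loop class is the unordered pair (E–P, E–E, P–P, E–N, P–N, N–N). N–N
loops are impossible under peak-anchored loop calling and are kept with a
warning so malformed inputs stay visible. Union loop sets collapse loops
whose anchor-start offsets both lie within a slack (default one bin) of each
other, transitively; merging is idempotent. The per-sample union signal is
the sum of overlapping sample-loop signal, zero when absent.

## Normalization and copy-number correction

Size factors use the median-of-ratios scheme: the reference is the
per-feature geometric mean over features positive in all samples, and a
sample's factor is its median ratio to the reference. Note the exact
equivariance of this estimator is relative: scaling one sample by *c* scales
its factor by *c* relative to every other factor and leaves the normalized
matrix unchanged up to one global constant, because the geometric-mean
reference moves with the scaled sample.

A sample's ploidy is the length-weighted mean total CN of its segments;
samples with more than 1,000 segments are flagged hyper-segmented (noisy
calls) and should be excluded. A feature's relative CN is the
length-weighted mean of `total_cn / ploidy` over overlapping segments.
Signal correction divides by `max(r, 1)` for peaks and by
`max(r1, 1) * max(r2, 1)` for loops — amplifications are corrected, losses
are untouched. The clamp on loop anchors mirrors the peak rule; correcting
losses as well would inflate signal at deleted loci where reads are already
sparse. Features on CN = 0 segments or without a CNV call become NaN and
stay NaN downstream. For the expression model, peak counts use the softer
normalization `count / (2 r + 1)` (with r the relative CN), whose
denominator is at least 1; the relative (ratio) scale is used rather than
absolute copies, consistent with defining gains as relative CN > 1.

## Contact matrices

Knight–Ruiz balancing uses the inner–outer Newton scheme with
conjugate-gradient inner solves; the input block is pre-scaled to unit mean
row sum (the balanced matrix is invariant to positive scaling) and bins with
zero marginal are masked out and reported as NaN. Convergence requires every
unmasked row sum within `tol` (default 1e-6) of 1. The O/E transform divides
each entry by the mean of its distance stratum over unmasked bins. The
compartment eigenvector is the leading eigenvector of the Pearson
correlation matrix of O/E columns; its sign is oriented by correlation with
a reference track of known polarity (positive = A/open). The eigenvector is
typically computed at coarse (e.g. 500-kb) resolution; resolution is the
caller's choice. Virtual-4C (EIS) profiles divide the anchor-bin row by the
total valid pairs and smooth with a centered rolling mean; the window
(default 5 bins, shrunken at the edges) is recorded in the profile object.

## Driver model

Genes pass an expression filter (TPM > 10 in more than 3 samples, both
strict). A peak is linked to a gene when it lies within 1 Mb of the TSS and
overlaps the non-promoter anchor of a loop whose other anchor overlaps the
promoter window. With at most five linked peaks the individual standardized
log2 signals enter the design; with more, the first five principal
components of the standardized log2 peak matrix. The response defaults to
log2(normalized count + 1) for variance stabilization (raw counts behind a
flag). The CN predictor is the gene-body relative CN. Samples with any
missing value are dropped per gene (minimum 10 complete samples).

LMG importance is computed by exact subset enumeration,

    LMG_j = sum over S not containing j of |S|! (p-|S|-1)! / p! * [R2(S+j) - R2(S)],

equivalent to averaging j's incremental R² over all p! orderings; in the
non-relative form the importances sum to the model R². Enumeration is
limited to p ≤ 8 (the design never exceeds 6 terms: 5 enhancer terms + CN).
A gene is copy-driven when CN carries the largest importance,
enhancer-driven when any enhancer term does, and unclassified when the
winning term's OLS coefficient p-value (two-sided t) is ≥ alpha (default
0.05). This significance rule is one deliberate operationalization of
"significantly explained"; a seeded bootstrap CI on the LMG difference
(`lmg_bootstrap_ci`, B = 1000) is provided as an alternative. Genes with
response variance ≤ 1 (log2 scale) are flagged as below the variance floor
but still reported. An optional cancer-type covariate residualizes the
response and all predictors on type indicators before fitting
(Frisch–Waugh), making the partition within-type.

## TME deconvolution

Accessibility is binary per cell population (peak called or not), mirroring
per-population peak calling. In a sample with at least 110 noncancer cells,
an E–P loop is *cell-type-specific* when the promoter anchor has both
H3K27ac and scATAC support and the enhancer anchor has H3K27ac support and
scATAC peaks of exactly one cell type; *shared* when both anchors are
supported in more than one cell type; *ambiguous* when neither anchor maps
to any scATAC peak, and also for edge cases the three rules do not cover
(e.g. scATAC support at one anchor only), with the per-anchor evidence
recorded. Samples below the cell minimum are skipped entirely. EIS–fraction
correlations use Spearman rho with average ranks on ties; both published
cutoffs (0.30 and 0.25) are exposed with 0.30 the default.

## Regulatory mutations

Variants require read depth strictly greater than 30 in both WGS and HiChIP.
Allelic enrichment is a two-sided Fisher exact test on
`[[wgs_ref, wgs_alt], [hichip_ref, hichip_alt]]` with BH correction across
tested variants and a separate direction flag (AF_HiChIP > AF_WGS); keeping
the test two-sided and applying direction as a filter is the conservative
choice when sidedness is not otherwise pinned down. Local signal contrast tiles
[pos − 1 kb, pos + 1 kb) into 20 × 100-bp bins, normalizes each sample's
window by its size factor and `max(r, 1)`, and applies a two-sided Welch
t-test of carrier versus non-carrier bin values pooled across samples
(positive t = carriers higher); with a single carrier the pooled-bin unit is
what makes the test defined, and a per-sample-mean alternative sits behind a
flag. Motif gain scans the reference and alternate 21-mers (variant at
position 11) on both strands at every offset; a placement is a hit when its
log-likelihood-ratio score's p-value under the background model is ≤ 0.01.
Score p-values come from the exact score distribution computed by dynamic
programming over positions (score keys merged at 1e-9), not from a normal
approximation. The background defaults to uniform base frequencies.
Nomination requires coverage pass, Fisher q < 0.05, the HiChIP direction and
a positive t score.

## SV rewiring

A loop belongs to an amplicon when both anchors overlap its intervals; it is
a neoloop when a breakpoint lies strictly between the anchors
(`anchor1.end <= b < anchor2.start`). This reference-coordinate rule is
exact for junctions internal to the amplified region and is an approximation
to calling loops on rearranged assemblies; inter-chromosomal junctions are
out of scope. Rates are neoloops per Mb of amplicon footprint. Class
comparisons use the two-sided Wilcoxon rank-sum test — exact enumeration
with midranks for groups of at most 10, normal approximation with tie
correction otherwise — followed by BH across class pairs. Co-amplification
frequency is the fraction of evaluable samples whose length-weighted total
CN exceeds 4.5 (the amplicon seed threshold) at both intervals.

## Cluster evaluation

Features on chrX/chrY or overlapping blacklist regions are dropped, then
features must reach a normalized count ≥ 3 in ≥ 2 samples. Values are
log2(x + 1); sample–sample correlation is pairwise-complete Pearson;
clustering is hierarchical on 1 − r with complete linkage (configurable; the
distance transform and linkage are recorded in the result), cut at k = the
number of unique class labels. Purity is the weighted majority fraction per
cluster; entropy is the class entropy per cluster normalized by log2 of the
class count, so (1, 0) is perfect and a single cluster over balanced classes
scores (0.5, 1). Subcompartment vectors are consumed as per-bin ordinal
ranks computed upstream.

## Synthetic cohort design

The generator emulates the statistical structure the analyses assume on one
30-Mb chromosome at 10-kb loop resolution, 60 samples over 4 cancer types by
default. Count-like data carry Poisson noise; peak signal carries log-normal
multiplicative noise; raw peak and loop counts scale with local DNA copies
so that CN correction has something real to remove. Every random draw flows
from one seed through named substreams, so each component regenerates
identically.

- *Enhancer-driven genes* (20) get three planted enhancer peaks (seven for
  every third gene, exercising the PCA path) whose log-signal follows a
  latent activity z ~ N(0,1) with slope 1.0 (noise SD 0.5); expression is
  log2-linear in z with slope 1.5 (noise SD 0.6); CN is near-diploid.
- *Copy-driven genes* (20) draw total CN from {1,...,8} per sample;
  expression is linear in relative CN (slope 1.2); their peaks carry no
  latent signal.
- *Null genes* (20) have noise-only expression (SD 1.2) and no planted E–P
  loops: the absence of regulatory linkage is what defines them as null, so
  their regression reduces to the CN term and the per-gene false-positive
  rate is the nominal alpha of the single winning-term test.
- Loop specificity labels are planted through the scATAC peak sets:
  malignant-specific and myeloid-specific enhancer peaks appear in exactly
  one population's set, shared peaks in all, and two genes' promoters and
  enhancers in none (ambiguous). Myeloid-labeled genes tie their latent
  activity to the sample's myeloid fraction, so their loop EIS tracks the
  fraction, as immune-gene expression does in real tumors.
- Variants (5% regulatory) shift the HiChIP allele fraction up by 0.3 and
  boost the carrier's 2-kb window signal threefold at 100-bp track
  resolution.
- Amplicons (six per class) are single intervals of 1–4 Mb with
  class-specific breakpoint counts and junction-spanning loop rates (cyclic
  6/Mb > complex 3.5 > BFB 2 > linear 0.8), reflecting the greater rewiring
  of circular amplicons; background loops are confined between breakpoints,
  so planted neoloop counts are exactly recoverable.

The generator does not emulate read-level data, assay-specific biases
(restriction-fragment structure, mappability), subclonal heterogeneity,
inter-chromosomal rearrangement or realistic motif landscapes. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative assumptions, not performance on real cohorts.

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 12–60 samples, 300 peaks,
~450 loops, 1,000 variants and 24 amplicons, with 200–300-bin contact
matrices — sizes chosen so the full suite completes in a few minutes while
every code path (PCA vs individual peaks, exact vs asymptotic rank-sum,
masked bins in balancing) is exercised. KR tolerance is 1e-6 on row sums;
LMG subset R² uses least squares with an intercept and raises on
rank-deficient designs, listing near-collinear columns; constant predictors
are dropped per gene before fitting; Fisher tests delegate to scipy (whose
two-sided p equals hypergeometric enumeration, asserted exhaustively for
totals ≤ 60); the exact rank-sum enumerates subsets with midranks because
library exact methods do not handle ties.

## Known limitations

- Neoloop identification in reference coordinates undercounts events whose
  junction partners lie on different chromosomes.
- The LMG enumeration is exponential in the number of predictors and capped
  at 8; designs with more enhancer terms must be reduced (the PCA path does
  this automatically).
- Pairwise-complete correlation can produce non-positive-definite
  correlation matrices in extreme missingness; clustering still works on
  1 − r but no repair is attempted.
- The two Spearman cutoffs (0.30 and 0.25) are both exposed because either
  is defensible for EIS–fraction screening; the stricter 0.30 is the
  default.
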