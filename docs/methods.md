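# Methods

This note documents the statistical models and numerical conventions of
cfmesa, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
the problem left the design open.

## Coordinate and format conventions

All genomic coordinates are 0-based half-open; chromosome names are
normalized to `chr`-prefixed form and ordered chr1..chr22, chrX, chrY.
Methylation calls use the MethylDackel-style bedGraph dialect (percent
column plus methylated/unmethylated counts); betas are always recomputed
from the counts, and the percent column is only cross-checked. Fragment
records are a genomic-coordinate, PAT-like TSV with one state symbol
(M/U/.) per reference CpG overlapped, validated against a CpG position
index. Missing values propagate as NA throughout; readers reject rather
than coerce.

## Differential methylation

Group comparisons use the two-sided Mann–Whitney U test on beta values.
For per-group n ≤ 8 the exact null enumeration is used; above that, the
tie-corrected normal approximation with continuity correction. The
absolute error of the approximation against the exact distribution at
n = 10 vs 10 is below 0.01 on the p-value scale; its *relative* error is
necessarily large in the extreme tail (any normal approximation is off by
orders of magnitude relative to exact p-values near the enumeration
minimum of ~1e-5), which matters only below p ≈ 0.005. CpG sites with
more than 10 % missing betas are removed before testing
(strictly-greater-than semantics, so exactly 10 % is retained).
Benjamini–Hochberg adjustment is applied separately to the CpG-level and
region-level families, since each is reported as its own analysis.

DMR discovery is mean-difference binary segmentation. CpGs are first
split into blocks wherever consecutive sites are more than `max_gap`
(default 300 bp) apart. Within a block, the sub-interval of at least
`min_cpgs` (default 10) CpGs maximizing the absolute difference of group
mean betas is located by exhaustive prefix-sum search; its boundaries are
then extended outward while adjacent CpGs keep a same-sign per-CpG
difference of at least `min_delta / 2`. The extension step matters: a
pure max-mean search systematically trims true regions to the minimum
length, because shorter intervals can ride upward noise — extension
restores full-region recovery without admitting null CpGs (which sit an
order of magnitude below the `min_delta / 2` bar at realistic depth). An
interval is reported iff its mean absolute difference reaches `min_delta`
(default 0.1); segmentation then recurses into the flanks. Every reported
region is rescored from scratch: per-sample mean beta over the region's
CpGs, Mann–Whitney across groups, BH over all reported regions — so the
reported p is exactly the test a reader would run on the per-sample
region means. The promoter retention filter keeps regions that overlap a
promoter, carry ≥ 10 CpGs, have adjusted p < 1e-5 and |Δβ| ≥ 0.1, and
excludes chrX (X-inactivation produces sex-driven differences there).
Promoters default to [TSS − 1000, TSS + 500) when derived from TSS
annotations. Z-scored summaries use the sample standard deviation
(ddof = 1); constant sites get z = 0.

## Fragmentomics

The window protection score at base p uses the even window
W = [p − w/2, p + w/2) with w = 120 bp (the long-fraction window of the
fragmentation literature; configurable). A fragment is *spanning* iff
start ≤ W.start and end ≥ W.end, and an *endpoint* fragment iff it is not
spanning and either its start or its last base lies in W — the two
classes are disjoint by construction, and the boundary cases (fragment
exactly equal to the window counts as spanning) are pinned by tests. The
implementation accumulates per-fragment difference arrays (closed integer
position runs derived from those conventions) and is tested for exact
equality against an O(n·m) per-position counting oracle. Region features
average the score over all bases of the region, informative or not.

Nucleosome occupancy is raw per-base fragment coverage divided by the
library-wide mean per-base coverage over a region universe, averaged over
1-kb windows centred on TSS/PAS midpoints. This replaces an external
nucleosome-positioning caller with the same averaging contract over the
same windows; it deliberately does not attempt single-dyad calling.
Regional methylation (CGI/DHS) is the unweighted mean of covered per-CpG
betas in the region — unweighted because the contract is an average of
site-level methylation, not of reads.

## Deconvolution

Fragment-level methylation classification uses the published U/X/M
defaults: at least 3 observed CpGs to be informative, U iff the
methylated fraction is ≤ 0.25, M iff ≥ 0.75, X between. Per-marker
U-fractions are U / (U + X + M) among informative fragments (a fragment
overlapping several markers counts in each; synthetic markers are
disjoint, so this only affects user data). The reference atlas is the
per-cell-type mean of per-sample U-fraction vectors, dropping markers
missing in any type. Mixture proportions solve nonnegative least squares
followed by normalization to the simplex — the post-hoc normalization
(rather than a simplex-constrained solve) keeps the solution identical to
the standard formulation and oracle-testable. Rank deficiency after
marker dropping raises an error naming the degenerate cell types.

The spike-in simulation holds out one target-type sample, rebuilds the
reference from the remaining samples, mixes the held-out sample's
fragments into a background pool at an exact fraction, and records the
estimated target proportion; per-sample marker/label assignments are
precomputed once so the 250 replicate deconvolutions are cheap. At the
default scale (7 cell types, 25 markers each, 20 000 fragments per
mixture) the recovery RMSE over the 0–10 % grid is ≈ 0.4 percentage
points.

## The stacked classifier

Each modality passes through: (1) a Mann–Whitney prefilter retaining the
top 3000/2500/200/200 features (CGI/DHS/occupancy/WPS) after dropping
features with > 20 % missing values and mean-imputing the rest with
training-fold means; (2) Boruta selection — per iteration, per-feature
permuted shadow copies are appended, a random forest ranks importances,
and a feature scores a hit when it beats the best shadow; hits are
confirmed/rejected by a BH-corrected two-sided binomial test against 0.5;
confirmed features are ranked by mean importance and backfilled from
tentative then prefilter rank to exactly the 100/100/20/80 marker
targets. When a modality has no more features than its target, selection
is the identity and the iterations are skipped.

The base estimator is a standardized L2-regularized logistic model with
balanced class weights. A gradient-boosted tree ensemble is available via
`MesaConfig(base_kind="gbt")`, but at cohort sizes near 40 the linear
model aggregates many weakly informative markers far more reliably (the
tree ensemble's greedy axis-aligned fits lose roughly 0.1 AUC on planted
multimodal signal at these sizes) and trains an order of magnitude
faster.

The meta-classifier combines the four base probabilities with a logistic
model whose weights are constrained non-negative and L2-anchored at equal
unit weights (anchor strength 50 on the mean-loss scale). The constraint
and anchor implement the classic stacking prescription that combiner
weights be non-negative, and they address a concrete pathology: under the
null, inner out-of-fold base probabilities are slightly anti-correlated
with the labels (the ordinary pessimism of cross-validated scores), and a
freely trained combiner either sign-flips modalities or zeroes all but a
noise-chosen one, driving the null AUC of the whole stack far below 0.5.
Anchored at the average, the combiner reduces to a calibrated mean of the
base probabilities when the inputs carry no information and reweights
them only with real likelihood evidence. The combined score is monotone
non-decreasing in every base probability. The meta is trained on inner
5-fold out-of-fold base probabilities within each training fold, so it
never sees resubstitution scores.

Evaluation is leave-one-out cross-validation with the entire selection
and fitting chain repeated inside every training fold; a guard asserts
the held-out sample never appears in a fold's training ids. The report
carries per-sample out-of-fold probabilities, the rank-statistic AUC
(ties counted half), sensitivity at 100 % specificity (positives strictly
above the best negative), ROC points, and a percentile-bootstrap AUC
interval — a single LOOCV yields one AUC, so the uncertainty statement is
a bootstrap over samples rather than a dispersion across folds.
Cross-cohort application maps features by id, imputes missing markers
with training means (erroring when more than half are absent), and never
refits.

Pooled LOOCV AUC is known to be pessimistically biased under the null:
each fold's model, having never seen the held-out sample, scores it
slightly against its own class (self-exclusion), and averaging four
modalities reduces noise while preserving that shared bias. With the
anchored combiner the measured null AUC at n = 40 is ≈ 0.46–0.48 with
spread close to the theoretical exchangeable-null standard deviation of
0.092; the residual ~0.03 pessimism is intrinsic to pooled LOOCV scoring
with in-fold selection, not a leakage artifact (leakage biases upward).

## Clinical correlation

The progression slope treats the full ALS-FRS-R score of 48 as the
pre-onset baseline, so slope = (48 − score at draw) / months since onset,
in points lost per month. Ranked gene tables accept any samples ×
candidates methylation matrix — single promoter CpGs or promoter means —
so both views of "gene methylation" run through the same interface.
Top-k tables report unadjusted p-values (they are exploratory rankings,
not discovery claims) alongside a Bonferroni column.

## Synthetic data

The generator encodes the study conditions: 19 cases vs 21 controls at
45x mean depth (Poisson per site), per-sample betas Beta(mc, (1 − m)c)
around the group mean m with concentration c = 50 — giving inter-sample
beta SD ≈ 0.05–0.07 at mid-range, so a planted Δβ of 0.10–0.15 is a
detectable but not trivial effect at n ≈ 20, matching the effect sizes
reported for promoter regions in this setting. Background CpG baselines
are the genome-like bimodal mixture 0.5·Beta(2,18) + 0.5·Beta(18,2);
CpGs inside planted regions draw mid-range baselines (clipped Beta(10,10))
because promoter DMRs live at intermediate methylation and a bimodal
baseline would clip the planted shift. Fragment lengths come from a
truncated-normal mixture (mono 170 ± 10, di 330 ± 15, di-weight 0.15,
truncation 100–500 bp) with centers at nucleosome dyads spaced 190 bp
plus Gaussian jitter. Atlas fragments carry molecule-level haplotypes
(all-U or all-M with 3 % per-CpG read error), which is what makes
fragment-level deconvolution identifiable. Clinical covariates couple to
promoter methylation through a Gaussian copula (Pearson r = 2 sin(πρ/6)
for target Spearman ρ); the ALS-FRS-R score at draw is back-solved from a
log-normal slope (median ≈ 0.7 points/month) and months since onset so
that (48 − score)/months reproduces the slope exactly after integer
rounding of the score; CSF pNfH is log-normal (median 2500 pg/mL)
coupled analogously.

What the generator does *not* emulate: genome sequence and CpG density
heterogeneity, SNP effects on methylation calls, batch and sex effects,
GC bias, realistic marker discovery (markers are planted disjoint and
balanced), or within-individual longitudinal structure. Tests passing on
this generator therefore certify the statistical machinery — calibration,
recovery, leakage-freedom, exactness of the fragment arithmetic — not
performance on real cfDNA, where effect sizes, dispersion, and marker
quality are less favorable.

## Problem sizes and determinism

Every generator and every stochastic component takes an explicit seed;
fixed seeds reproduce byte-identical outputs. The classifier studies in
the test suite and acceptance script run with Boruta capped at 10
iterations over 20-tree forests and feature counts of a few hundred per
modality — sizes chosen so planted signals are comfortably inside the
detectable regime while a full LOOCV stays in the tens of seconds. The
exact configurations are in the tests and in `scripts/acceptance.py`.

## Known limitations

* The DMR segmentation is a re-implementation in the spirit of
  metilene-style binary segmentation, scored by Mann–Whitney on region
  means; it omits the original 2D Kolmogorov–Smirnov co-test.
* Sensitivity at 100 % specificity is a discontinuous statistic at small
  n; with 19 positives the resolution is ≈ 5 percentage points.
* The exact-permutation Spearman p-value is enumerated only up to n = 9
  pairs (9! orderings); above that a t approximation is used.
* Deconvolution assumes the atlas U-fractions are noiseless on the scale
  of the sample vector; at very low fragment counts per marker the NNLS
  estimates acquire a positive bias at true fraction 0 (measured ≈ 0.1 %
  at the default scale).
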