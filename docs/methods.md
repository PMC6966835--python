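# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the points where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Count model and differential expression

Counts are modelled per gene as negative binomial with mean μ and
dispersion φ, variance μ + φμ²; the biological coefficient of variation
is BCV = √φ. Dispersion is estimated by conditional maximum likelihood
on library-equalised pseudo-counts: counts are scaled to the geometric
mean of the TMM-effective library sizes and rounded, making per-sample
means exchangeable within a group so that the likelihood conditional on
the gene's group total depends on φ alone. The common dispersion
maximises the conditional log-likelihood summed over genes and groups;
tagwise dispersions maximise each gene's own conditional likelihood plus
`prior_weight` (default 10) times the across-gene average — an
empirical-Bayes shrinkage toward the common value. Both are located on
a 400-point log-spaced grid over [1e-6, 20] with 3-point parabolic
refinement (grid spacing ~4%, refined accuracy well below the Monte
Carlo error of any test that consumes it).

The exact test conditions on a gene's total pseudo-count: under the
null the group-1 sum follows the ratio of two NB pmfs with sizes
n_g/φ, and the two-sided p-value sums all outcomes no more probable
than the observed one (the φ→0 limit is the exact Poisson-conditional
binomial test, verified against a closed-form oracle). For totals above
20 000 the support is windowed to ±40 conditional standard deviations;
the excluded tail mass is far below double precision. Fold changes use
a prior count of 0.125 per group to avoid infinities; per-group
expression is reported as log2 of the group mean CPM (the alternative,
mean of log2 CPM, is a documented non-choice since the emulated study
does not say which it used).

Multiple testing uses Benjamini–Hochberg step-up for DE and
Benjamini–Yekutieli (BH × Σ 1/i) for differential dispersion. DE calls
require q < 0.05 and linear |FC| > 1.5, with a relaxed 1.2 threshold
available for miRNAs/lincRNAs. Summary statistics follow the emulated
study's conventions: DE proportions are percentages truncated (not
rounded) to two decimals; the mean absolute fold change is the
arithmetic mean of 2^|log2FC|.

## Differential dispersion

The DD test is a per-gene likelihood ratio: the null fits group-specific
means with a shared φ, the alternative group-specific means and
group-specific φ; both carry per-sample log-library-size offsets so the
mean model absorbs depth, and the statistic (referred to χ²(1)) responds
to variability only — a simplification of covariate-capable dispersion
modelling down to the two-group design actually analysed, with outlier
protection delegated to the upstream IQR capping. Means are profiled
out at fixed φ by a fixed-point iteration on the score equation
(m = Σ y_i w_i / Σ L_i w_i, w_i = 1/(1 + φ m L_i)); the outer search is
bounded Brent on log φ in [1e-8, 50] with tolerance 1e-8, max 100
iterations. The profile likelihood carries a Cox–Reid adjustment
(−½ log of the mean parameter's observed information per group): without
it the dispersion MLE at 11–12 replicates is biased low and the test
runs anticonservative; with it the null p-values are uniform (checked by
KS in the suite). `disp_log2fc = log2(φ₂/φ₁)` with φ floored at 1e-8.
Count-model stages (DE, DD) run on raw counts with TMM offsets;
correlation stages run on capped CPM — capped counts would not be
NB-distributed.

## Preprocessing conventions

TMM: reference sample = the one whose 75th count-proportion percentile
is closest to the across-sample mean; genes with a zero count in either
sample are dropped; rank-based double trimming of 30% on M and 5% on A;
weights are the inverse delta-method variance of M; factors rescaled to
geometric mean 1. Quantiles everywhere are linear/type-7. The
expressed filter keeps mRNA/miRNA genes with CPM > 1 in at least
⌈0.5·n⌉ samples and every lincRNA ("average expression above 1 CPM in
half the samples" is internally contradictory; the per-sample reading is
used). Capping replaces values outside the Tukey fences (1.5·IQR) by
the 10th/90th percentile of the *within-fence* values: taking the
percentile over the full vector would re-cap its own output even in the
simplest one-outlier case, whereas the within-fence variant is
idempotent there and on realistic expression vectors; zero-IQR vectors
are left alone, as is anything shorter than 4. Capping operates on CPM
after normalisation, per gene across the contrast's samples — the
emulated study does not state its order, so this one is fixed here and
used everywhere.

## PCIT, edge typing, seed validation, RIF

PCIT trio tolerances use signed partial correlations divided by signed
direct correlations, averaged over the trio's three edges, and are
applied in absolute value; trios containing an exactly zero direct
correlation contribute no invalidation (a zero edge cannot explain
others away), and off-diagonal |r| = 1 is clamped to 1 − 1e-12 before
partials. The implementation vectorises over the conditioning gene;
an independently coded triple-loop oracle pins its behaviour in the
suite. Whether the emulated analysis applied PCIT significance to the
miRNA–mRNA pairs or only the r < −0.5 cut is ambiguous; both are applied
by default, with `apply_mask_to_mirna=False` to disable the mask.
Candidate nodes are all expressed miRNAs plus the DE mRNAs of the
contrast.

Seed validation is strict Watson–Crick 7mer-m8 only: the reverse
complement of mature positions 2–8 (RNA or DNA alphabet, case-
insensitive) must occur verbatim on the UTR sense strand (1-based
coordinates; ambiguity codes never match; no G:U wobble, no 6mer/8mer
classes). With isoform UTRs, a match in any record validates the edge
(longest record scanned first); how isoform UTRs were collapsed
originally is unstated, so the any-record rule is the documented choice.

RIF expression scales e1/e2 are within-condition mean log2(CPM + 0.25)
of each DE gene, and r1/r2 are within-condition Pearson correlations on
capped CPM over that condition's 11 or 12 samples, unfiltered by PCIT
(also unstated originally; both choices are surfaced in the API). Raw
and standardised (sample-SD z) scores are emitted since the original
report's scale is unstated. Reversing the contrast negates both scores
exactly.

## Modules and traits

Signed adjacency ((1+r)/2)^β with β = 16, standard TOM, average-linkage
clustering of 1 − TOM. Dynamic tree cutting is replaced by a static
cut — the exact dynamic variant is unstated — placed at the midpoint of
the widest gap in the upper half of the merge heights: tight
co-expression joins sit well below the near-1 heights at which
unstructured genes chain together, and the widest-gap rule finds that
separation without a hand-tuned constant (an explicit `cut_height`
overrides it). Clusters below 30 genes are unassigned; modules whose
eigengene correlation exceeds 0.75 (dissimilarity < 0.25) merge
iteratively, closest pair first. Eigengenes are the first right
singular vector of the gene-standardised module matrix, unit variance,
signed so the mean member correlation is non-negative. miRNA-only
modules are dropped from trait association. Kleinberg hub centrality
on a symmetric adjacency reduces to the principal eigenvector (computed
by dense symmetric eigendecomposition, scaled to max 1 per module);
`networkx.hits` serves as the independent cross-check in the suite.

## Synthetic-data generator

The generator emulates the structure of the fasting-vs-fed muscle
experiment, and its defaults are the study conditions: groups of 11 and 12 samples (one fasted animal
excluded in the original design), biotype BCVs 0.53 (mRNA), 0.37
(miRNA), 1.15 (lincRNA), baseline log2 CPM 6/4.5/1.5 with SD 2
(reproducing the observed abundance ordering mRNA > miRNA > lincRNA and
the inverse abundance–variability trend), library sizes log-uniform
±30% around 1e6, 10% DE genes at |log2FC| = 1 (the printed mean |FC| of
DE genes is about 2), 5% DD genes at a 4-fold dispersion shift, 5
regulator miRNAs × 10 targets, 3 planted 50-gene modules, 6 traits of
which 3 couple to modules at R² = 0.6.

Unstructured genes are exact Gamma–Poisson (NB). Genes that need
*correlated* biological noise — module members and regulator targets —
use a log-normal biological component moment-matched to the NB
dispersion (σ² = log(1+φ), mean 1, CV² = φ), because a shared Gaussian
factor can be embedded in it exactly; first and second moments match the
NB everywhere. A regulator's latent activity is its own realised log2
expression (shared noise), and `coupling_strength` is defined as the
fraction of a target's biological log-variance explained by the
regulator, so the planted correlation approaches −√coupling before
count-sampling attenuation; at the default 0.8 the planted edges sit
near r ≈ −0.7 and overwhelmingly clear the r < −0.5 retention rule. A
literal "mean depressed proportionally to coupling" parameterisation
would strand planted correlations at ≈ −0.49 under the mRNA BCV of
0.53, defeating the generator's purpose of producing detectable planted
edges. Planted regulator targets double as DE genes because the network
stage correlates miRNAs against DE mRNAs only; planted gene categories
are otherwise disjoint so recovery metrics are unconfounded, and
planted targets/regulators/module members have their baseline abundance
floored at the biotype mean (co-expression is undetectable by any
method when shot noise dominates). Planted repression is identical in
both conditions, so planted regulators carry little differential
wiring — RIF is exercised on explicitly rewired profiles in the suite
instead.

Sequences: mature miRNAs are random 22-mers (RNA alphabet) with
distinct regulator seeds; UTRs are random DNA of the configured length
(default 500) with the regulator's site overwritten at a recorded
1-based position in each target, and rejection sampling guarantees no
unplanned occurrence of any regulator site in any UTR. Phenotypes:
coupled trait = √R² × module eigengene + √(1−R²) × standard noise.

What the generator does **not** emulate: read-level artifacts
(alignment, GC, length biases), batch effects, isoform structure,
condition-dependent regulation, and correlated traits. Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under a faithful count model, not robustness to those
real-data complications.

## Problem sizes and determinism

The suite and the acceptance script use 2000-gene simulations for
calibration (type-I error, LRT uniformity, FDR), 400–600 genes for
recovery, and the default 580-gene dataset for the end-to-end run —
sizes at which Monte Carlo error is small relative to every asserted
tolerance while the whole suite stays fast. All randomness flows from
explicit seeds (`numpy.random.default_rng`); the same seed yields
byte-identical generator output and pipeline tables, which the suite
asserts.

## Known limitations

- DE/DD power at 11–12 replicates with BCV ≥ 0.5 is modest; planted
  recall figures reflect that, and the end-to-end network recall is
  therefore reported both conditional on the DE-called candidate set
  (what the network stage controls) and unconditionally.
- The dispersion LRT uses the χ²(1) asymptotic; the Cox–Reid adjustment
  makes it calibrated at these sample sizes, but very small groups
  (< 3 samples) are rejected rather than approximated.
- PCIT is O(n³); candidate sets beyond a few thousand nodes would need
  blocking, which is out of scope.
- The static-cut + merge module detector is a deliberate simplification
  of dynamic tree cutting; on data without a height-gap structure the
  cut falls back to an essentially arbitrary point in the upper height
  range.
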