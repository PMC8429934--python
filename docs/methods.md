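# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should know
about.

## Synthetic cohorts

Expression is generated as convex mixtures of cell-type expression
programs: a genes × cell-types reference `S` is built from disjoint marker
blocks (each of the `n_cell_types = 8` programs overexpresses its own
`markers_per_type = 25` genes by a factor drawn uniformly from 5–50 over a
shared log-normal baseline; remaining genes are background, identical
across programs). Per-sample mixing fractions are Dirichlet draws with
cluster-specific concentration vectors, and
`expression = S · fractionsᵀ`, multiplied by log-normal noise of standard
deviation `noise_sd` (default 0.1, i.e. ~10% multiplicative noise).

Two planted-structure presets exist:

- **Disjoint-block design (default):** each of the 3 planted patterns is
  concentrated (4.0 vs 0.3) on its own block of cell types. This is the
  configuration used for the clustering and deconvolution recovery
  studies, where pattern identity must be unambiguous.
- **Two-program gradient (`CohortConfig.two_program`):** the cell types
  split into programs A and B (first/second half); the 3 patterns
  interpolate from A-rich (concentration 10 vs 0.8) through balanced to
  B-rich. The latent infiltration score is the standardized A-minus-B
  mass. This is the configuration for score-recovery studies: the derived
  per-sample score contrasts two gene programs, so a recoverable planted
  axis must itself be a two-program contrast. Under the disjoint design no
  fixed axis is recoverable even in principle — the 2-way gene clustering
  then contrasts a seed-dependent pair of patterns.

The batch effect is applied on the log2 scale per cohort as
`x' = m_g + shift_b + scale_b (x − m_g)` (defaults: shift 0.8, scale 1.2
on the second cohort), matching the location/scale model the correction
assumes. Survival times are exponential with hazard
`h0 · exp(surv_beta · latent)` (`h0 = 0.02`/month, `surv_beta = 0.7`);
censoring is independent exponential whose rate is solved by bisection so
the expected censored fraction equals `censor_rate` (default 0.3). The MAF
plants per-sample nonsynonymous counts as Poisson(group rate × 38 Mb) with
group rates 2.0 vs 1.0 events/Mb for the low/high latent-score groups,
silent records at 30% of the nonsynonymous rate, and driver genes mutated
Bernoulli per group (TP53 0.38/0.14, MAP3K1 0.06/0.14 for low/high —
frequencies of the order reported for breast tumors).

One global seed fans out to per-stage child seeds through
`numpy.random.SeedSequence`, so stages are reproducible independently.

**What the generator does not emulate:** negative-binomial read-count
noise, gene–gene correlation beyond the mixture structure, copy-number or
subclonal architecture, informative censoring, microarray/RNA-seq platform
differences beyond location/scale. Recovery results on these cohorts
therefore show that the algorithms are implemented correctly and behave
as designed under their own model assumptions — not that the biological
conclusions transfer to any real cohort.

## Batch correction

Standard parametric empirical-Bayes location/scale adjustment, no
covariates: per-gene standardization against the batch-weighted grand mean
and pooled within-batch variance; per-(gene, batch) location γ̂ and scale
δ̂²; normal and inverse-gamma priors fitted across genes by moments; the
usual fixed-point iteration for the posteriors; reconstruction on the
input scale. Genes with zero pooled variance are passed through with a
warning. After adjustment each gene is recentred to its pre-correction
grand mean — EB shrinkage otherwise leaves a small per-gene offset — which
makes the "grand mean preserved" property exact and changes nothing else.

Two caveats worth knowing. The procedure is not exactly idempotent:
shrinkage leaves residual batch contrasts of order (1−w)·γ̂, so a second
application still changes the data slightly (tested as a strong
contraction, second-pass change < 5% of the first). And testing *batch*
on the corrected data is statistically degenerate: the correction removes
the *estimated* batch means, so same-data batch t-tests are deflated
(conservative) by construction, and on an equal-size held-out replicate
they are inflated by ≈ √(1 + n_eval/n_train). Post-correction batch
p-values are therefore never uniform at matched cohort sizes; the tests
check contraction of the batch separation instead. ComBat-style recovery
simulations use iid-gene log-expression (the model the correction
assumes): on mixture cohorts all genes share the sample-level mixing
fractions, so pooled per-gene p-values are strongly correlated and
Kolmogorov–Smirnov uniformity checks are invalid even on null data.

## TIME profiling

**ssGSEA.** Genes are ranked per sample by expression (descending, ties
broken by gene id); the score is the sum over the ranked list of the
running normalized in-set weighted mass minus the running out-of-set mass.
In-set weights are `rank^α` of the rank values n..1, so scores depend on
ranks only and are invariant to monotone transforms of a sample's values.
Default α = 0.25 with matrix-level (max−min) normalization — the common
default for immune-signature scoring. The stromal/immune scores are
unnormalized ssGSEA scores on the two gene sets so the identity
`estimate = stromal + immune` is exact; the cosine purity transform is
applied only when the caller supplies the published platform-specific
constants, because those constants were fitted on a specific array
platform.

**Deconvolution.** Mixture and reference are z-scored over the shared
signature genes; a linear ν-SVR is fitted for each ν in {0.25, 0.5, 0.75}
and the ν minimizing reconstruction RMSE kept; negative coefficients are
clamped to zero and renormalized to fractions. The permutation p-value
compares each sample's reconstruction correlation against a shared null of
`n_perm` random mixtures resampled from the full expression matrix. The
reference passed to the solver should be the marker-gene submatrix (the
way leukocyte signature matrices are constructed); fitting over background
genes is an order of magnitude slower with no accuracy gain. The
conventional p < 0.05 post-filter is exposed on the result
(`filter_significant`) and applied by the pipeline before clustering.

## Pattern discovery

Consensus clustering with PAM inside the resampling loop: for each of
`reps` repetitions (pipeline default 200; 1,000 is the conventional
published setting), ⌈0.8·n⌉ samples are drawn without replacement and
k-medoids run on Euclidean distances with a deterministic greedy build
step plus swap phase — the only randomness is the subsample draw.
Consensus(i, j) is the co-cluster count over the co-sample count; the
final partition cuts an average-linkage tree of 1−consensus at k. "PAM
with Ward linkage" is contradictory (PAM has no linkage), so linkage
enters only in consolidating the consensus matrix. k is selected from the
growth of the area under the consensus CDF: delta-area(k) is the relative
area increase versus k−1 (the area itself for the smallest k), and the
chosen k is the smallest k after which the gain drops below the elbow
threshold (default 0.1, exposed in config; ties go to the smaller k).

## Signature derivation and the ICI score

The moderated one-way F test shrinks per-gene residual variances toward a
scaled inverse-chi-square prior whose hyperparameters (d₀, s₀²) are
moment-matched on log residual variances (digamma/trigamma relations;
trigamma inverted by bracketed root-finding). If the observed spread of
log-variances is at or below the sampling spread, d₀ = ∞ and all variances
shrink to s₀². `d0_override=0` reproduces the ordinary F exactly and is
used as the no-shrinkage oracle in tests. Fold change across >2 groups is
the maximum pairwise ratio of group means on the linear scale; DEGs
require adjusted p < 0.05 AND fold change > 1.5, both strict.

Samples are Ward-clustered on z-scored DEG expression into two gene
clusters, oriented so cluster "B" has the higher mean immune score when an
immune score is available (deterministic labelling). Genes are split into
signature A (correlation with the A→0/B→1 label ≥ 0, ties and degenerate
genes logged) and signature B (negative). Boruta reduces each signature:
every iteration appends shuffled shadow copies of **all** original
features, fits a 500-tree random forest (impurity importance), counts a
hit when a feature beats the best shadow, and decides features by a
two-sided binomial test at α = 0.01 with Bonferroni adjustment across
features; leftover tentative features are resolved by comparing median
importance against the median best-shadow importance. Two details matter:
shrinking the shadow pool to undecided features lets spuriously in-sample-
correlated noise outrun a degenerate max-shadow bar, and without the
multiple-comparison adjustment the sequential testing confirms such
features. Even so, the single most lucky noise feature (|r| ≈ 0.25 at
n = 200) is genuinely in-sample predictive and is confirmed in a minority
of runs — an inherent property of importance-based all-relevant selection,
not a defect.

`pc1_score` z-scores the genes, takes each sample's coordinate on the
first right singular vector (samples as observations), and fixes the sign
so the score correlates positively with the per-sample mean z-expression
of the set — PC sign is otherwise backend-dependent. The ICI score is
`PC1_A − PC1_B` per sample; it is antisymmetric under swapping the
signatures and invariant to gene and sample order. Dichotomization into
high/low groups uses the maximally selected log-rank cutpoint.

## Survival analysis

Kaplan–Meier, log-rank and Cox fits are computed by lifelines (partial
likelihood with Efron tie handling; backward elimination by AIC when
`stepwise` is requested). The X-tile surrogate scans every candidate
cutpoint (midpoints of consecutive sorted unique scores) between the 10th
and 90th score percentiles and returns the cut maximizing the log-rank
chi-square; the associated p-value is maximally selected and is reported
with that caveat rather than corrected, matching common usage. The
nomogram maps covariate values to points,
`points_j(x) = 100·|β_j|·(x − ref_j) / max_k(|β_k|·range_k)` with the
reference at the low-risk end of each covariate's observed range, and
total points back to survival through `S₀(t)^exp(lp)` at 3/5/10 years
(horizons beyond follow-up yield NA). Calibration bins samples by
predicted survival at the horizon (quantile bins, default 3) and compares
against the within-bin KM estimate. Age enters the nomogram continuously;
a dichotomized variant can be passed by the caller. Group comparisons
elsewhere use the Wilcoxon rank-sum (2 groups) or Kruskal–Wallis (>2).

## Enrichment

Two-class ranking uses the signal-to-noise statistic with each group's
standard deviation floored at 0.2·|mean| (0.2 when the mean is zero), ties
ordered by gene id. The GSEA running sum increments by |stat|^p
(normalized) on set members and 1/(N−|S|) off-set; ES is the signed
maximum deviation. The null is gene-set permutation (random same-size
draws from the ranked universe, default 1,000; the pipeline default is 100
for runtime), NES = ES over the mean |null ES| of matching sign, nominal p
one-sided within the matching sign, and FDR q by the standard sign-pooled
NES convention. Weight p = 1 by default.

## Mutation landscape

TMB counts MAF records whose Variant_Classification is in the
nonsynonymous set {Missense, Nonsense, Nonstop, Splice_Site,
Translation_Start_Site, Frame_Shift_Del/Ins, In_Frame_Del/Ins} divided by
the interrogated exome size (default 38 Mb, configurable; the splice-site
convention follows maftools). Samples listed but absent from the MAF get
TMB 0. The "detection limit" of variant calling is an upstream input
assumption, not re-implemented. Mutation frequencies binarize multiple
hits per gene/sample; per-gene group comparisons use the Pearson
chi-square without continuity correction (df = 1), NA on zero margins,
BH-adjusted across testable genes; score associations use Spearman rank
correlation with average ranks.

## Problem sizes in the test and acceptance runs

Recovery studies run at the sizes stated with their checks: deconvolution
at n = 60 with 8 cell types; consensus k-selection over 20 seeds at
n = 150 with 200 repetitions; batch-shift recovery at 500 genes × 100
samples; Cox recovery over 50 seeds at n = 500; the end-to-end score
chain at n = 300 × 2,000 genes; the pipeline smoke run at 300 × 2,000
with 100 permutations and 200 consensus repetitions. Unit tests replicate
the same properties at smaller seed counts, chosen so the whole suite
runs in a few minutes; thresholds in those tests are set from the
statistical power of the reduced design, not tuned to outcomes.
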