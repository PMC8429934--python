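# ici-landscape

Immune-cell-infiltration (ICI) landscape analysis for bulk tumor
transcriptomes. The package profiles the tumor immune microenvironment
(TIME) of each sample, groups samples into recurrent infiltration patterns,
condenses the patterns into a single per-sample score, and relates that
score to survival, pathway activity and tumor mutation burden. It is aimed
at computational biologists who want the full workflow — from expression
matrix to prognostic score — as a tested, scriptable Python library rather
than a chain of R packages.

## What it computes

Given a genes × samples expression matrix `X` (TPM-like), a clinical table
and (optionally) somatic mutations in MAF format:

1. **Batch correction** — parametric empirical-Bayes location/scale
   adjustment on log2 data: gene *g* in batch *b* is modelled as
   `x = α_g + γ_gb + δ_gb ε`, with a normal prior on γ and an
   inverse-gamma prior on δ² estimated across genes by moments.
2. **TIME profiling** — per sample: rank-based single-sample gene-set
   enrichment (ssGSEA running sum with weights `rank^α`, α = 0.25);
   stromal/immune scores whose sum is the ESTIMATE-style score; and
   leukocyte fractions by linear ν-support-vector regression against a
   reference signature matrix, with a permutation p-value per sample.
3. **Pattern discovery** — consensus clustering: PAM (k-medoids,
   Euclidean) on subsampled cohorts, consensus matrix of co-clustering
   frequencies, final assignment by average-linkage cut, and the number of
   patterns chosen from the delta-area elbow of the consensus CDF.
4. **ICI score** — moderated one-way F across patterns (empirical-Bayes
   variance shrinkage), DEGs filtered at adjusted p < 0.05 and fold change
   > 1.5, Ward gene-clustering of samples into two transcriptional groups,
   genes split into signatures A/B by the sign of their correlation with
   that grouping, Boruta all-relevant reduction, and finally

   `ICI score_i = PC1_A(i) − PC1_B(i)`

   the difference of each sample's first-principal-component coordinates
   on the two signatures.
5. **Survival** — Kaplan–Meier curves, log-rank tests, a maximally
   selected log-rank cutpoint (X-tile-style dichotomization), Cox models
   with backward-AIC selection, a points-based nomogram for 3/5/10-year
   survival and its calibration curve.
6. **Enrichment & mutation** — two-group GSEA (signal-to-noise ranking,
   gene-set permutation null, NES/FDR), tumor mutation burden
   (nonsynonymous events per megabase), per-gene mutation-rate chi-square
   comparisons and Spearman score–TMB association.

A synthetic-cohort generator (`ici_landscape.synthetic_cohort`) plants all
of the structure the analysis assumes — mixing fractions with a 3-pattern
Dirichlet design, a two-cohort batch effect, survival driven by a latent
infiltration axis, group-specific mutation rates — and returns the ground
truth, so every stage is covered by recovery tests.

## Worked example

Discover infiltration patterns on a planted 3-pattern cohort
(`examples/03_discover_patterns.py`):

```bash
$ python examples/03_discover_patterns.py
area under the consensus CDF per k: {2: 0.464, 3: 0.669, 4: 0.727, 5: 0.771, 6: 0.808}
delta-area per k: {2: 0.464, 3: 0.444, 4: 0.087, 5: 0.06, 6: 0.047}
chosen k = 3
ARI against the planted patterns at k=3: 1.000
```

Moving from k=2 to k=3 still increases the consensus-CDF area by 44%, but
k=4 adds only 8.7% — the elbow selects the planted k=3, and the consensus
assignment matches the planted patterns exactly (adjusted Rand index 1.0).
Deriving the score on a two-program cohort
(`examples/04_ici_score.py`) prints:

```
DEGs passing adjP<0.05 & FC>1.5: 200
signature A/B sizes: 100/100 (post-Boruta 100/100)
correlation of ICI score with the planted latent axis: +0.997
```

i.e. the PC1-difference score recovers the planted infiltration gradient
almost perfectly. The other examples cover simulation, TIME profiling,
survival modelling, GSEA, mutation burden and the end-to-end pipeline
(`ici-landscape run --config pipeline.yaml --out DIR --seed 7` or
`examples/08_full_pipeline.py`).

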