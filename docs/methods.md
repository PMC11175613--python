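# Methods

This document records the statistical model the package implements,
the assumptions behind it, its default parameters, the scope of the
synthetic-cohort generator, the numerical choices that make results
reproducible, and the limitations of both.

## 1. Question and design

The package evaluates Brain Age — the out-of-fold prediction of
chronological age from brain features — as a biomarker of fluid
cognition. The evaluation has four stages:

1. generate (or load) a cohort with phenotypes and named feature sets;
2. fit nested cross-validated penalised models predicting age
   (→ Brain Age) and fluid cognition (→ Brain Cognition);
3. derive the four Brain Age indices per participant per model;
4. partition the variance of fluid cognition explained by
   {age, index} and {age, index, Brain Cognition} into unique and
   common effects.

The quantity of interest is the *unique* effect of each index: the ΔR²
it adds to a model of cognition that already contains age.

## 2. Synthetic cohort generator

### Generative model

All latents are standard normal and mutually independent unless
stated. With `z` standardized chronological age (age drawn uniformly
on the configured range, default 36–100):

```
B_age      = √g · z   + √(1−g) · η              (brain-aging latent)
A_k        = √q_k · B_age + √ρ_k · B_cog + √(1−q_k−ρ_k) · η_k
cognition* = −√s_a · z + √s_b · B_cog + √(1−s_a−s_b) · ε
```

where `g` = `brain_aging_strength`, `q_k` = `age_latent_fidelity`,
`ρ_k` = `age_cog_overlap` for feature set k, `s_a` =
`cognition_age_share`, `s_b` = `cognition_brain_share`, and `B_cog` is
a brain-cognition latent independent of age. Standardized cognition is
mapped to score points as `100 + 15 · cognition*`. The age–cognition
association is generated negative (cognition declines with age).

Each feature column loads on exactly one latent — the set's aging
latent `A_k` (variance share `age_signal_share` per column) or `B_cog`
(share `brain_signal_share`) — plus an additive sex shift
(`sex_effect_size`) and idiosyncratic noise. When both shares are
positive the columns split roughly half and half between the two
groups.

The overlap share `ρ_k` is the generator's key lever: it lets a set's
aging signal carry cognition-relevant variance that chronological age
itself does not. A set with low `q_k` and high `ρ_k` predicts age
poorly, yet its Brain Age retains unique information about cognition —
the dissociation between age accuracy and biomarker value that the
analysis is designed to measure.

### Closed-form ground truth

Columns within a load-group are exchangeable, so the population
best-linear-predictor of any target from a set is a function of the
two group means only. Every designed R² therefore follows from a 2×2
covariance solve; for a single group with per-column share `a` and no
overlap this reduces to

```
κ(m, a) = m·a / (1 + (m−1)·a)
R²(age | set k) = g · q_k · κ(m_k, a_k)
```

`generate_cohort` returns these values alongside the data
(`GroundTruth`), and the test suite verifies them against large-sample
OLS and Monte-Carlo estimates.

### Scope

The generator is deliberately linear-Gaussian: linear loadings,
homoscedastic noise, additive sex effect, uniform age. It reproduces
the *variance structure* of an aging-cohort study — heterogeneous
set sizes and signal strengths, shared versus unique cognition
variance, an age-declining composite — not the spatial or temporal
structure of real imaging data. Connectivity sets are generated as
wide column collections (not as correlation matrices); the
`vectorize_offdiagonal`/`fisher_z` utilities exist for adapting real
connectivity matrices into the documented feature layout.

### Default study layout

504 participants (293 female), 18 feature sets: ten 379-column task
contrast sets, three task-FC and one rest-FC connectivity sets
(71,631 pair features each at full scale, i.e. a 379-region
parcellation; desk-scale runs pass a smaller dimension), and four
structural sets (cortical thickness 148, surface area 148, subcortical
volume 19, total brain volume 5). Defaults: `s_a = 0.32`,
`s_b = 0.15`, `g = 0.85`; per-category shares as in
`brainage_eval.cohort.study_spec`.

## 3. Prediction engine

### Preprocessing (per training fold)

All parameters are estimated on the training rows of the current fold
and transferred to its validation/test rows:

1. connectivity sets only: PCA to `n_components` (default 75) scores;
2. per-column OLS residualisation on sex;
3. centering and scaling by the sample standard deviation (ddof = 1).

A switch (`sex_before_pca`) residualises sex from the raw columns
before the PCA instead; either order is defensible for correlational
features. Zero-variance columns are dropped at fit time with a
warning.

### Elastic Net

The objective is scikit-learn's parameterisation:

```
min_β  ‖y − Xβ‖² / (2n) + α·l1·‖β‖₁ + ½·α·(1−l1)·‖β‖₂²
```

The full grid is 70 log-spaced α ∈ [0.1, 100] × 25 linear
l1 ∈ [0, 1]; the reduced grid (7 × 5) covers the same ranges for
desk-scale runs. `l1 = 0` is solved exactly by the penalised normal
equations (one eigendecomposition serves the whole α path); `l1 > 0`
uses coordinate descent with warm-started α paths.

### Nested cross-validation and stacking

Five outer folds for unbiased test predictions; within each outer
training set, five inner folds for hyperparameter selection
(preprocessing re-fitted inside every inner fold). Selection maximises
mean inner-validation R²; ties break to the first grid point in
ascending (α, l1) order. The winning configuration is refit on the
whole outer-training set.

Stacked models use one column per member feature set — the refit
level-1 model's predictions on the outer-training rows — as the
second-level design, tuned on a *fresh* set of inner folds drawn
independently of the level-1 folds, and applied to the level-1 models'
outer-test predictions. Eight standard stacks are resolved from the
category tags (all, all-minus-task-FC, all-minus-task-contrast,
non-task, rest+task-FC, task-contrast+FC, task-contrast, task-FC). An
optional variant (`oos_stacking`) feeds the stack cross-validated
(out-of-sample) training-row predictions instead of in-sample ones.

Feature importance is the full-data refit coefficient vector
(back-projected through the PCA as Σ_components |loading| × coefficient
for connectivity sets), with rank stability summarised by Spearman ρ
over the C(5,2) = 10 outer-fold coefficient pairs.

## 4. Brain Age indices

For each age model: Brain Age (out-of-fold prediction), Brain Age Gap
(Brain Age − age), Corrected Brain Age, and Corrected Brain Age Gap.
Penalised predictions shrink toward the training mean, making the raw
gap correlate negatively with age. The correction fits
`BrainAge = β₀ + β₁·age` by OLS on each outer fold's *training*
predictions and applies `(BrainAge − β₀)/β₁` to that fold's test
predictions. Within a training fold this restores slope 1/intercept 0
exactly; out of fold a residual age dependence remains (−0.20 vs
−0.55 raw in the seed-1 study run). A near-zero fitted slope
(constant predictor) makes the correction undefined and raises an
error.

## 5. Commonality analysis

For regressor blocks V = {1..k} over fluid cognition, the R² of every
non-empty subset model is combined into one component per non-empty
subset S:

```
C(S) = Σ_{T ⊆ S} (−1)^{|S|−|T|+1} · R²(V \ T)        (R²(∅) = 0)
```

Singletons are unique effects (the ΔR² of adding that block last);
larger subsets are common effects; all components sum to the
full-model R² (checked to 1e−8 at report time). Negative commons
(suppression) may be zeroed and the positive components rescaled to
preserve the full R² (`zero_and_rescale`); the package reports both
forms. Unique effects carry a hierarchical F-change test:

```
F = (N − k₂ − 1) · ΔR² / (k_change · (1 − R²_full))
```

on (k_change, N − k₂ − 1) degrees of freedom.

Variants: a quadratic age block {age, centered age²} treated as one
unit, and ridge-based subset R²s with a single cross-validated penalty
reused across subsets.

## 6. Numerical choices

- All randomness flows from `numpy.random.default_rng(seed)`; stage
  seeds are derived (folds: seed+1000, importance refit: seed+2000).
  Identical configurations reproduce every CSV byte-for-byte.
- PCA loading signs are fixed by making each component's
  largest-magnitude entry positive.
- Standardisation uses the sample standard deviation (ddof = 1).
- Connectivity vectorisation takes the upper triangle (k = 1) in
  row-major order; a 379-region matrix gives 71,631 features.
- Out-of-fold R² is 1 − SS_res/SS_tot (may be negative); Pearson r is
  reported NaN for constant predictions.
- Coordinate descent runs with tol = 1e−8, max_iter = 100,000.

## 7. Limitations

- Synthetic cohorts share only the variance structure of real imaging
  studies; effect sizes at desk scale are design choices, and absolute
  numbers (R², MAE) should not be read as empirical claims about any
  real population.
- The generator is linear and Gaussian; nonlinear aging trajectories,
  site effects, motion confounds and non-additive sex effects are out
  of scope.
- Commonality components beyond three blocks grow combinatorially and
  are increasingly unstable in small samples; the package computes
  them exactly but reports only 2- and 3-block decompositions in the
  standard analyses.
- The F-change test assumes fixed regressors and Gaussian errors;
  with generated (estimated) regressors like Brain Age it is the
  conventional approximation, not an exact test.
- Stacking uses in-sample level-1 training predictions by default
  (matching common practice); the `oos_stacking` variant exists
  because in-sample stacking features can overweight overfit members.
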