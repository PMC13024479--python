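# Methods

## Problem setting

`alscreen` implements a screening pipeline for latent physiological
dysregulation (allostatic load) predicted from psychometric survey data in a
two-wave longitudinal cohort. Individuals carry a baseline wave (M2) and a
follow-up wave (M3) of p survey predictors, plus biomarker panels for three
physiological domains measured at both waves: inflammatory (CRP, IL-6,
fibrinogen), metabolic (glucose, triglycerides, HDL, SBP, DBP, waist
circumference), and neuroendocrine (24-h urinary cortisol, DHEA-S). Biomarkers
define the outcome labels only; they are never predictors, and the deployed
model consumes follow-up survey predictors alone.

## Target constructions

Three canonical operationalizations of domain-level high risk are computed
independently per domain and wave:

- **Q (quantile)**: a biomarker flags risk when it lies in the cohort's upper
  quartile (lower quartile for protective markers, i.e. HDL and DHEA-S); the
  label is 1 when at least half the domain's markers flag (2/3 INFL, 3/6 META,
  1/2 NEURO).
- **Z (z-score)**: each biomarker is standardized within wave, protective
  markers are sign-reversed, the composite is the mean signed z-score, and the
  label flags composites at or above the composite's empirical 0.75 quantile.
- **C (clinical)**: fixed guideline cutoffs (CRP > 3.0 mg/L, IL-6 > 3.19 pg/mL,
  fibrinogen > 400 mg/dL, glucose ≥ 126 mg/dL, triglycerides ≥ 150 mg/dL,
  HDL < 40/50 mg/dL for men/women, SBP ≥ 140 mmHg, DBP ≥ 90 mmHg, waist
  > 102/88 cm for men/women) plus sex-stratified cohort quartiles for cortisol
  (upper) and DHEA-S (lower), then the same majority rule.

Numerical conventions: empirical quantiles use linear interpolation between
order statistics (the default of mainstream numerical stacks), and threshold
comparisons are inclusive (≥ / ≤) exactly as the definitions state. With a
tie-free composite of length 584 the Z rule therefore flags exactly 146
individuals: the interpolated 0.75 quantile falls strictly between order
statistics 438 and 439, leaving ranks 439–584 flagged. Entirely tied
composites flag everyone under the inclusive comparison and emit a degeneracy
warning, as does any threshold carrying more than 30 % of the cohort. Constant
biomarker columns yield all-zero quantile flags with a warning rather than
flagging the whole cohort. Individuals with a missing biomarker are excluded
from that domain's labels (complete-case per domain, recorded in a mask);
outcome imputation is deliberately avoided.

Because the NEURO quantile and clinical rules differ only in pooled versus
sex-stratified quartiles, their prevalences agree closely but not exactly; the
test suite bounds the gap at 0.04, which covers the stratification effect at
n = 584 with the generator's sex shifts.

## Teacher models

For each (domain, definition), a two-stage longitudinal teacher is fit under
a shared stratified 5-fold plan:

1. a random forest on the baseline predictors against the baseline label,
   emitting strictly out-of-fold baseline probabilities p̂^M2;
2. a random forest on the follow-up predictors augmented with p̂^M2, against
   the follow-up label, emitting strictly out-of-fold outcome probabilities p̃
   and per-fold impurity importances (the baseline-probability channel is
   excluded from the importance vector).

Forests use 200 trees, balanced class weights, and seed 42 (fold-offset for
distinct per-fold forests). Stage-2 training rows take their p̂^M2 from the
single shared out-of-fold vector, so no individual's probability ever comes
from a model trained on that individual. Missing predictors are imputed with
training-fold medians only. The baseline estimator is a forest with the same
hyperparameters because the targets are defined at both waves; with
independent waves (autocorrelation 0) the augmented stage is statistically
indistinguishable from a follow-up-only forest, which the suite checks.

Within a definition, one fold plan is shared by the teacher, all baselines,
and both students. Since the student predicts the three domains jointly, the
plan stratifies on the joint three-domain label pattern (patterns rarer than
the fold count pooled into one bucket); per-domain positive rates then remain
approximately, not exactly, balanced across folds.

## Ranking, parsimony, pruning

Fold importances are averaged into a per-domain ranking (ties broken
lexicographically for determinism). Nested top-K subsets are re-fit with the
identical protocol over a grid (default K ∈ {5, 10, …, 100}, capped at p) and
the mean out-of-fold AUC across the three domains is recorded per K. K* is
the smallest grid K with AUC(K) ≥ max AUC − ε; the default tolerance
ε = 0.005 AUC encodes "near-optimal at minimal dimensionality" and is
exposed in the run configuration. K* selection is a pure function of the
curve and ε and is monotone non-increasing in ε.

After K* is chosen, the per-domain models (final teachers and all
baselines) each keep their own domain's top-K* features, since they are
fit independently per domain. The multi-head student needs one joint input
set; it receives K* features built by round-robin interleaving of the three
domain rankings, which guarantees each head's strongest predictors are
represented (a scale-weighted merge can starve the weakest domain). For
parameter-recovery analyses a single merged ranking is also provided, built
by normalizing each domain's mean importances to sum to one and averaging —
the normalization prevents a domain with larger absolute impurity scales
from dominating, which matters because a predictor informative for one
domain is near-noise for the others individually.

## Student models and distillation

The student is a compact multi-head network: input → 128 → 128 (ReLU,
dropout 0.25 after each hidden layer) → 32-dimensional linear embedding →
one sigmoid head per domain. It is trained with AdamW (lr 1e-3, decoupled
weight decay 1e-4 on weights), batch size 64, at most 200 epochs, early
stopping with patience 20 on an inner 10 % validation split of each outer
training fold, monitored on the composite loss; the best-validation weights
are restored. Features are standardized with training-fold statistics
(forests receive raw features). The loss per individual is

    Σ_d [ λ·BCE(y_d, p̂_d) + (1 − λ)·(p̂_d − p̃_d)² ],

with the mixing coefficient λ = 0.7 by default; λ = 1 with no teacher input
is the direct student used as a baseline. Predicted probabilities are clipped
to [1e-7, 1 − 1e-7] inside the cross-entropy. The network, backpropagation,
and AdamW are implemented directly in numpy, which keeps training
bit-reproducible under a fixed seed on a single CPU.

Strict per-epoch monotonicity of the minibatch training loss is not
enforceable; the suite checks the weaker convergence diagnostic that the
final epoch's mean training loss does not exceed the first epoch's. Inference
is guarded: the fitted student refuses input frames carrying baseline-wave
or teacher-probability columns.

## Baselines and metrics

The comparison menu fits, under the same plan and features: a follow-up-only
random forest, L2-regularized logistic regression, elastic net (mixing ratio
0.5), and the direct student. Linear models are standardized and their
penalty strength is chosen by 3-fold inner CV on training folds.

AUC is the Wilcoxon–Mann–Whitney rank statistic with ties counted one half;
it agrees exactly with exhaustive pair counting. Average precision is the
step-wise non-interpolated convention (tied scores enter as one threshold) —
the convention under which a random ranking's expected AP equals the positive
rate; the small-sample positive bias of this estimator decays with n, and the
null-convergence check uses n = 1000 where the bias is below 0.005. AP lift
is AP divided by prevalence. Permutation importance is the mean decrease in
AUC over 10 seeded permutations of one column, aggregated across model
variants by plain mean/std with per-variant non-zero flags.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
three latent dysregulation factors (one per domain). Follow-up factors are
ρ·baseline + √(1−ρ²)·innovation with ρ = `wave_autocorrelation` (default
0.7). Informative predictors load 1.0 on their factor and 0.3 on a
neighbouring factor, with idiosyncratic noise of sd 0.6 — psychometric
predictors are scale scores (item aggregates), so their reliability is high
(≈ 0.74 here). Redundant predictors are informative columns plus noise of
sd 0.5; remaining predictors are pure noise. Every idiosyncratic component
persists across waves with the same ρ, so the whole predictor matrix has
realistic cross-wave correlation and ρ = 1 freezes predictors across waves.
Biomarkers are linear in their domain factor with sign matching the
direction flag, scaled by `effect_size` (default 1.5) against unit-sd noise,
and mapped onto clinical measurement scales (e.g. CRP mean 2.6, sd 1.4 mg/L)
so the C-definition cutoffs fall inside the bulk of each distribution. Sex
is Bernoulli(0.5) and shifts waist, HDL, cortisol and DHEA-S means so
sex-specific rules are exercised. Missingness is MCAR, confined to
predictors (default rate 0.05; biomarkers are complete). The default cohort
size is 584 individuals.

What the generator does not emulate: questionnaire semantics and item-level
structure, informative missingness, attrition, mixed measurement scales
(ordinal/categorical items), non-linear factor–biomarker links, and
between-domain biomarker correlation beyond the factor cross-loadings.
Passing tests therefore demonstrate that the pipeline's machinery is correct
and recovers planted structure under its own assumptions — not that any
particular discrimination level is attainable on a real cohort.

## Problem sizes in the test suite

The simulation experiments run at the study's cohort size (n = 584) with
compact predictor universes: 10 informative + 40 noise predictors for
parameter recovery (20 seeds) and the plateau check (grid 5–50), 50
predictors with redundancy for the distillation comparison (10 seeds), and
an all-noise cohort for the null-safety check. The end-to-end smoke test
uses n = 200, p = 60, 3 folds. These sizes were chosen so the statistical
properties of interest are well-resolved while the whole suite runs in
minutes on one CPU.

## Known limitations

- Dysregulation is binarized; the continuous composites are computed but not
  modelled directly.
- The filter module ships pattern-based exclusion categories, not a survey
  dictionary; real deployments must supply their own pattern lists and
  variant-collapse maps.
- The elastic-net mixing ratio is fixed at 0.5 rather than tuned.
- The clinical neuroendocrine rules are cohort-relative (sex-stratified
  quartiles), so the C definition is not fully external for that domain.
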