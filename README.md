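# alscreen

Non-invasive screening for latent physiological dysregulation (allostatic
load) from high-dimensional psychometric survey data, in a two-wave
longitudinal cohort design.

The package is aimed at biostatisticians and epidemiological modellers who
have a baseline wave (M2) and a follow-up wave (M3) of survey predictors
plus biomarker panels, and want a compact, deployable model that screens for
follow-up dysregulation using follow-up survey answers alone. It implements
a teacher–ranking–pruning–student pipeline:

1. **Targets.** Binary high-risk labels per physiological domain —
   inflammatory (CRP, IL-6, fibrinogen), metabolic (glucose, triglycerides,
   HDL, SBP, DBP, waist), neuroendocrine (cortisol, DHEA-S) — under three
   canonical allostatic-load constructions: cohort quartiles (Q), signed
   z-score composites (Z), and clinical cutoffs (C). E.g. the Z label is
   y = I( S ≥ Q₀.₇₅(S) ) with S the mean signed z-score over the domain's
   biomarkers.
2. **Teachers.** For each (domain, definition), a two-stage longitudinal
   random forest: a baseline-wave forest g(X^M2) produces out-of-fold
   baseline risk p̂^M2, and the outcome forest f(X^M3, p̂^M2) produces
   out-of-fold follow-up risk p̃ plus per-fold feature importances — all
   under one shared stratified 5-fold plan, with no probability ever coming
   from a model that saw that individual.
3. **Ranking and parsimony.** Fold importances are averaged into a stable
   ranking; nested top-K subsets are refit and K* is the smallest K with
   AUC(K) ≥ max AUC − ε (default ε = 0.005).
4. **Student.** A compact multi-head network (input → 128 → 128 → 32-dim
   embedding → 3 sigmoid heads) on the K* follow-up predictors, trained with
   the composite distillation loss
   Σ_d [ λ·BCE(y_d, p̂_d) + (1−λ)·(p̂_d − p̃_d)² ], λ = 0.7, so longitudinal
   information is used in training but never required at inference.
5. **Evaluation.** Out-of-fold AUC, average precision (AP), prevalence π and
   AP lift (= AP/π) for the student against random-forest, L2-logistic,
   elastic-net and direct-network baselines under the identical fold plan.

Real cohort data of this kind are access-restricted, so the package ships a
first-class synthetic cohort generator (latent dysregulation factor per
domain, autocorrelated across waves; informative/redundant/noise predictors;
biomarkers on clinical scales with sex-shifted means) that every stage is
developed and tested against. See `docs/methods.md` for the full model
description and design decisions.

## Worked example

```python
import alscreen as als
from alscreen.teacher import TeacherHyper
from alscreen.student import StudentConfig

cfg = als.RunConfig(
    cohort=als.CohortConfig(n_individuals=300, n_predictors=60, n_informative=9,
                            n_redundant_per_informative=1, missing_rate=0.02, seed=1),
    definitions=("Q",), k_folds=5, seed=7,
    teacher=TeacherHyper(n_trees=100),
    student=StudentConfig(max_epochs=60, seed=7),
    k_grid=[5, 10, 15, 20, 30, 45, 60],
    out_dir="demo_run",
)
bundle = als.run_pipeline(cfg)
print(bundle["manifest"]["k_star"])   # {'Q': 10}
```

The run writes `parsimony_curve.csv`:

```
 K  mean_auc  mean_ap  selected
 5     0.863    0.759     False
10     0.894    0.799      True
15     0.893    0.797     False
20     0.896    0.802     False
30     0.898    0.800     False
45     0.891    0.791     False
60     0.885    0.773     False
```

Mean out-of-fold AUC across the three domains rises until the ~9 planted
informative predictors are covered and then plateaus; K* = 10 is the
smallest subset within ε = 0.005 of the maximum, a 6× reduction of the
predictor space at no cost. `model_menu.csv` then compares the menu on the
pruned sets (excerpt, quantile definition):

```
      model domain   auc    ap  prevalence  ap_lift
      rf_m3   META 0.918 0.828       0.267    3.103
 mlp_direct   META 0.919 0.845       0.267    3.169
mlp_distill   META 0.921 0.853       0.267    3.198
    teacher   META 0.920 0.825       0.267    3.093
```

An AP lift of 3.2 means high-risk individuals are 3.2× more concentrated at
the top of the student's ranking than under random ordering at prevalence
0.267. `full_vs_kstar.csv` shows the teacher's AUC/AP on FULL vs the K*
subset (pruning helps in every domain on this cohort), and `ap_lift.csv`
isolates the distilled student's lift table.

The same stages are available as CLI subcommands
(`alscreen simulate | filter | targets | teach | prune | distill | evaluate | run-all`),
e.g. `alscreen simulate --out cohort/ --n 584` then
`alscreen targets --cohort cohort/ --definition Z --wave M3 --out labels.csv`.

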