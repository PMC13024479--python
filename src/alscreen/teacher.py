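"""Two-stage longitudinal teacher models.

For each physiological domain and target definition, a high-capacity
random-forest teacher is fit in two stages under a shared stratified
cross-validation plan:

* stage 1 fits a baseline-risk forest g_d on the baseline-wave predictors
  against the baseline-wave label and emits strictly out-of-fold baseline
  probabilities;
* stage 2 fits the outcome forest on the follow-up predictors augmented
  with the stage-1 baseline probability, against the follow-up label, and
  emits strictly out-of-fold outcome probabilities plus per-fold feature
  importances.

Every probability attached to an individual comes from a model whose
training fold excluded that individual.  Missing predictor entries are
imputed by training-fold medians only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold


class FoldError(ValueError):
    pass


@dataclass(frozen=True)
class TeacherHyper:
    """Random-forest hyperparameters (defaults: 200 trees, balanced class
    weighting, seed 42)."""

    n_trees: int = 200
    class_weight: str | None = "balanced"
    seed: int = 42


@dataclass
class FoldPlan:
    """A stratified k-fold assignment shared by every model of a comparison."""

    k: int
    assignment: np.ndarray  # fold id per individual
    labels: np.ndarray      # stratification labels used
    seed: int

    @property
    def n(self) -> int:
        return len(self.assignment)

    def split(self):
        for f in range(self.k):
            test = np.flatnonzero(self.assignment == f)
            train = np.flatnonzero(self.assignment != f)
            yield f, train, test


def make_fold_plan(labels, k: int = 5, seed: int = 42) -> FoldPlan:
    """Stratified k-fold assignment, reproducible under ``seed``.

    Per-fold positive counts differ by at most one individual from perfect
    proportionality.
    """
    y = np.asarray(labels).astype(int)
    n = len(y)
    if k < 2:
        raise FoldError("k must be at least 2")
    if n < 2 * k:
        raise FoldError(f"n = {n} too small for k = {k} stratified folds")
    classes = np.unique(y)
    if len(classes) < 2:
        raise FoldError("stratified folds require both classes present")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros((n, 1)), y)):
        assignment[test] = f
    return FoldPlan(k=k, assignment=assignment, labels=y, seed=seed)


@dataclass
class TeacherResult:
    oof_baseline: np.ndarray          # p-hat at baseline wave, strictly OOF
    oof_outcome: np.ndarray           # p-tilde at follow-up, strictly OOF
    fold_importances: pd.DataFrame    # k x p, impurity importances of stage 2
    stage2_models: list = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)


def _median_impute(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Impute both arrays with training-column medians (leak-free)."""
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    def fill(a):
        a = a.copy()
        idx = np.where(np.isnan(a))
        a[idx] = np.take(med, idx[1])
        return a
    return fill(train), fill(other)


def _check_fold_classes(y_tr: np.ndarray) -> None:
    if len(np.unique(y_tr)) < 2:
        raise FoldError(
            "a training fold contains a single class; use a larger cohort "
            "or fewer folds"
        )


def _forest(hyper: TeacherHyper, fold: int) -> RandomForestClassifier:
    # fold offset keeps per-fold forests distinct but reproducible
    return RandomForestClassifier(
        n_estimators=hyper.n_trees,
        class_weight=hyper.class_weight,
        random_state=hyper.seed + fold,
        n_jobs=1,
    )


def fit_teacher(
    X_M2: pd.DataFrame,
    X_M3: pd.DataFrame,
    y_M2,
    y_M3,
    plan: FoldPlan,
    hyper: TeacherHyper | None = None,
) -> TeacherResult:
    """Fit the two-stage teacher under a shared fold plan.

    Stage-1 baseline probabilities for stage-2 training rows come from the
    same out-of-fold vector, so no individual's probability was produced by
    a model trained on that individual.
    """
    hyper = hyper or TeacherHyper()
    y2 = np.asarray(y_M2).astype(int)
    y3 = np.asarray(y_M3).astype(int)
    if not (len(X_M2) == len(X_M3) == len(y2) == len(y3) == plan.n):
        raise ValueError("rows of X_M2, X_M3, y_M2, y_M3 and plan must align")
    features = list(X_M3.columns)
    A2 = X_M2[features].to_numpy(dtype=float)
    A3 = X_M3.to_numpy(dtype=float)
    n = plan.n

    # stage 1: baseline-risk estimator on (X_M2, y_M2)
    oof_baseline = np.full(n, np.nan)
    for f, train, test in plan.split():
        _check_fold_classes(y2[train])
        tr, te = _median_impute(A2[train], A2[test])
        model = _forest(hyper, f)
        model.fit(tr, y2[train])
        oof_baseline[test] = model.predict_proba(te)[:, 1]

    # stage 2: outcome forest on ([X_M3, p-hat], y_M3)
    aug = np.column_stack([A3, oof_baseline])
    oof_outcome = np.full(n, np.nan)
    importances = np.zeros((plan.k, len(features)))
    models = []
    for f, train, test in plan.split():
        _check_fold_classes(y3[train])
        tr, te = _median_impute(aug[train], aug[test])
        model = _forest(hyper, 100 + f)
        model.fit(tr, y3[train])
        oof_outcome[test] = model.predict_proba(te)[:, 1]
        importances[f] = model.feature_importances_[: len(features)]
        models.append(model)

    return TeacherResult(
        oof_baseline=oof_baseline,
        oof_outcome=oof_outcome,
        fold_importances=pd.DataFrame(importances, columns=features),
        stage2_models=models,
        feature_names=features,
    )
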