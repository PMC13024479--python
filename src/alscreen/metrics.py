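"""Evaluation metrics and comparison baselines.

AUC is implemented as the Wilcoxon–Mann–Whitney rank statistic (probability
that a random positive outranks a random negative, ties counted 1/2) and
average precision as the step-wise, non-interpolated sum of precision
weighted by recall increments — the convention under which a random ranking
has expected AP equal to the positive-class prevalence.  AP lift is AP
divided by prevalence.

``fit_baselines`` fits the comparison menu — random forest on follow-up
predictors only, L2 logistic regression, elastic net, and a direct (non-
distilled) neural network — under a shared fold plan, emitting strictly
out-of-fold probabilities for each.  ``permutation_importance`` measures the
drop in AUC after permuting one predictor column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegressionCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from alscreen.teacher import FoldPlan, TeacherHyper, _check_fold_classes


class MetricError(ValueError):
    pass


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if not np.isin(y, (0, 1)).all():
        raise MetricError("labels must be binary")
    return y


def auc(scores, labels) -> float:
    """Wilcoxon–Mann–Whitney AUC with ties counted one half."""
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def average_precision(scores, labels) -> float:
    """Step-wise (non-interpolated) average precision.

    AP = sum over descending score thresholds of precision at the threshold
    times the recall increment.  Tied scores enter as a single threshold.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise MetricError("average precision requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted)
    n_seen = np.arange(1, len(y) + 1)
    # last index of each distinct-score block: a valid threshold
    last_of_block = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    precision = tp[last_of_block] / n_seen[last_of_block]
    recall = tp[last_of_block] / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def ap_lift(ap: float, prevalence: float) -> float:
    """Enrichment of average precision over a random ranking."""
    if not 0.0 < prevalence < 1.0:
        raise MetricError("prevalence must lie strictly between 0 and 1")
    return ap / prevalence


# --- baseline model menu --------------------------------------------------

def _rf_baseline(hyper: TeacherHyper, fold: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=hyper.n_trees,
        class_weight=hyper.class_weight,
        random_state=hyper.seed + fold,
        n_jobs=1,
    )


def _linear_pipeline(kind: str, seed: int, inner_cv: int = 3) -> Pipeline:
    if kind == "logit_l2":
        clf = LogisticRegressionCV(
            Cs=10, cv=inner_cv, l1_ratios=(0.0,), scoring="roc_auc",
            max_iter=5000, random_state=seed, use_legacy_attributes=False,
        )
    elif kind == "elastic_net":
        clf = LogisticRegressionCV(
            Cs=5, cv=inner_cv, solver="saga", l1_ratios=(0.5,),
            scoring="roc_auc", max_iter=5000, random_state=seed, tol=1e-3,
            use_legacy_attributes=False,
        )
    else:  # pragma: no cover - internal
        raise ValueError(kind)
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", clf),
        ]
    )


def fit_baselines(
    X_M3: pd.DataFrame,
    y_M3,
    plan: FoldPlan,
    hyper: TeacherHyper | None = None,
    include_mlp: bool = True,
) -> dict[str, np.ndarray]:
    """Out-of-fold probabilities for the comparison model menu.

    All models share the fold plan and the feature set.  Linear models are
    standardized and their regularization strength is chosen by inner CV on
    the training folds; the forest receives raw (median-imputed) features.
    """
    hyper = hyper or TeacherHyper()
    y = _as_binary(y_M3)
    A = X_M3.to_numpy(dtype=float)
    n = plan.n
    out = {
        "rf_m3": np.full(n, np.nan),
        "logit_l2": np.full(n, np.nan),
        "elastic_net": np.full(n, np.nan),
    }
    for f, train, test in plan.split():
        _check_fold_classes(y[train])
        med = np.nanmedian(A[train], axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        tr = np.where(np.isnan(A[train]), med, A[train])
        te = np.where(np.isnan(A[test]), med, A[test])
        rf = _rf_baseline(hyper, f)
        rf.fit(tr, y[train])
        out["rf_m3"][test] = rf.predict_proba(te)[:, 1]
        for kind in ("logit_l2", "elastic_net"):
            pipe = _linear_pipeline(kind, hyper.seed + f)
            pipe.fit(A[train], y[train])
            out[kind][test] = pipe.predict_proba(A[test])[:, 1]
    if include_mlp:
        from alscreen.student import StudentConfig, train_student

        cfg = StudentConfig(lambda_mix=1.0, seed=hyper.seed)
        res = train_student(X_M3, y.reshape(-1, 1), None, plan, cfg)
        out["mlp_direct"] = res.oof_probs[:, 0]
    return out


def score_table(oof: dict[str, np.ndarray], labels) -> pd.DataFrame:
    """AUC / AP / prevalence / AP lift per model on shared labels."""
    y = _as_binary(labels)
    prev = float(y.mean())
    rows = []
    for model, scores in oof.items():
        ap = average_precision(scores, y)
        rows.append(
            {
                "model": model,
                "auc": auc(scores, y),
                "ap": ap,
                "prevalence": prev,
                "ap_lift": ap_lift(ap, prev),
            }
        )
    return pd.DataFrame(rows).set_index("model")


def permutation_importance(
    model,
    X: pd.DataFrame,
    y,
    features: list[str] | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean/std decrease in AUC after permuting each predictor column.

    ``model`` must expose ``predict_proba`` over the columns of ``X``.
    """
    y = _as_binary(y)
    rng = np.random.default_rng(seed)
    features = features or list(X.columns)
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise MetricError(f"feature(s) {missing} absent from model input")
    A = X.to_numpy(dtype=float)

    def _score(arr):
        frame = pd.DataFrame(arr, columns=X.columns)
        return auc(model.predict_proba(frame)[:, 1], y)

    base = _score(A)
    col_index = {c: i for i, c in enumerate(X.columns)}
    rows = []
    for feat in features:
        j = col_index[feat]
        drops = []
        for _ in range(n_repeats):
            perm = A.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            drops.append(base - _score(perm))
        rows.append(
            {"feature": feat, "delta_auc": float(np.mean(drops)),
             "delta_auc_std": float(np.std(drops, ddof=0))}
        )
    return pd.DataFrame(rows).set_index("feature")


def aggregate_permutation_importance(
    per_variant: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Aggregate per-variant Delta-AUC tables across model variants.

    Returns the mean and std of each feature's mean Delta AUC across the
    variants (e.g. the nine definition x domain models), plus one boolean
    presence column per variant marking non-zero importance.
    """
    features = sorted({f for df in per_variant.values() for f in df.index})
    mat = pd.DataFrame(
        {name: df["delta_auc"].reindex(features).fillna(0.0) for name, df in per_variant.items()},
        index=features,
    )
    out = pd.DataFrame(
        {
            "mean_delta_auc": mat.mean(axis=1),
            "std_delta_auc": mat.std(axis=1, ddof=0),
        }
    )
    for name in per_variant:
        out[f"in_{name}"] = mat[name] > 0
    return out.sort_values("mean_delta_auc", ascending=False)
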