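"""Stable feature ranking and tolerance-based parsimony selection.

Fold-level importances from the outcome-stage teacher are averaged into a
global ranking per (domain, definition).  Nested top-K subsets are then
re-fit under the identical fold plan, the mean out-of-fold AUC across
domains is recorded per K, and K* is the smallest grid value whose AUC is
within a fixed tolerance epsilon of the grid maximum — parsimony is
preferred over marginal accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from alscreen.metrics import auc, average_precision
from alscreen.teacher import FoldPlan, TeacherHyper, fit_teacher


class RankingError(ValueError):
    pass


def aggregate_ranking(fold_importances: pd.DataFrame) -> list[str]:
    """Features sorted by mean importance across folds, descending.

    Ties break lexicographically on the feature name for determinism.
    Importances must be nonnegative (impurity importances are).
    """
    vals = fold_importances.to_numpy(dtype=float)
    if (vals < 0).any():
        raise RankingError("negative importances: contract violation upstream")
    mean = fold_importances.mean(axis=0)
    order = sorted(mean.index, key=lambda name: (-mean[name], name))
    return list(order)


@dataclass
class ParsimonyCurve:
    k_grid: list[int]
    auc_by_k: dict[int, float]
    ap_by_k: dict[int, float]
    epsilon: float
    k_star: int
    definition: str = ""
    per_domain_auc: dict[int, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": self.k_grid,
                "mean_auc": [self.auc_by_k[k] for k in self.k_grid],
                "mean_ap": [self.ap_by_k[k] for k in self.k_grid],
                "selected": [k == self.k_star for k in self.k_grid],
            }
        )


def select_k_star(auc_by_k: dict[int, float], epsilon: float) -> int:
    """Smallest K whose AUC is within ``epsilon`` of the grid maximum."""
    if not auc_by_k:
        raise RankingError("empty parsimony curve")
    if epsilon < 0:
        raise RankingError("epsilon must be nonnegative")
    best = max(auc_by_k.values())
    for k in sorted(auc_by_k):
        if auc_by_k[k] >= best - epsilon:
            return k
    raise AssertionError("unreachable: the argmax always satisfies the bound")


def sweep_parsimony(
    rankings: dict[str, list[str]],
    X_M2: pd.DataFrame,
    X_M3: pd.DataFrame,
    y_M2: dict[str, np.ndarray],
    y_M3: dict[str, np.ndarray],
    plans: dict[str, FoldPlan],
    k_grid: list[int],
    epsilon: float = 0.005,
    hyper: TeacherHyper | None = None,
    definition: str = "",
) -> ParsimonyCurve:
    """Refit teachers on nested top-K subsets and select K*.

    ``rankings`` maps each domain to its aggregated feature ranking; each
    K point refits the two-stage teacher per domain on that domain's top-K
    features under the identical fold plan, and the curve records the
    unweighted mean OOF AUC/AP across domains.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    p_min = min(len(r) for r in rankings.values())
    if k_grid[0] < 1 or k_grid[-1] > p_min:
        raise RankingError(
            f"k_grid must lie within [1, {p_min}] (surviving feature count)"
        )
    auc_by_k: dict[int, float] = {}
    ap_by_k: dict[int, float] = {}
    per_domain: dict[int, dict[str, float]] = {}
    for k in k_grid:
        aucs, aps, dom_auc = [], [], {}
        for domain, ranked in rankings.items():
            chosen = set(ranked[:k])
            # keep original column order so the top-p subset reproduces the
            # full fit exactly
            top = [f for f in X_M3.columns if f in chosen]
            res = fit_teacher(
                X_M2[top], X_M3[top], y_M2[domain], y_M3[domain],
                plans[domain], hyper,
            )
            a = auc(res.oof_outcome, y_M3[domain])
            aucs.append(a)
            aps.append(average_precision(res.oof_outcome, y_M3[domain]))
            dom_auc[domain] = a
        auc_by_k[k] = float(np.mean(aucs))
        ap_by_k[k] = float(np.mean(aps))
        per_domain[k] = dom_auc
    k_star = select_k_star(auc_by_k, epsilon)
    return ParsimonyCurve(
        k_grid=k_grid, auc_by_k=auc_by_k, ap_by_k=ap_by_k,
        epsilon=epsilon, k_star=k_star, definition=definition,
        per_domain_auc=per_domain,
    )
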