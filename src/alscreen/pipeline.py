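"""End-to-end pipeline orchestration.

Runs filter -> targets -> two-stage teachers -> stable ranking ->
parsimony sweep -> student distillation + baseline menu -> metric tables,
from a single serializable configuration, persisting every intermediate
artifact as delimited tables plus a JSON run manifest.

Within a target definition, one fold plan is shared by every model (teacher,
baselines, both students) so that performance differences reflect modeling
choices rather than data partitioning.  Because the student predicts all
three domains jointly, the shared plan stratifies on the joint pattern of
the three domain labels (rare patterns pooled), which keeps per-domain
positive rates approximately balanced across folds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from alscreen.cohort import Cohort, CohortConfig, generate_cohort, read_cohort
from alscreen.filters import FilterConfig, apply_filters
from alscreen.metrics import ap_lift, auc, average_precision, fit_baselines
from alscreen.ranking import aggregate_ranking, sweep_parsimony
from alscreen.student import StudentConfig, train_student
from alscreen.targets import DEFINITIONS, build_targets, default_thresholds
from alscreen.teacher import FoldPlan, TeacherHyper, fit_teacher, make_fold_plan

logger = logging.getLogger("alscreen")

DOMAINS = ("INFL", "META", "NEURO")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """A fully serializable pipeline run configuration."""

    cohort: CohortConfig | str = field(default_factory=CohortConfig)
    definitions: tuple[str, ...] = ("Q", "Z", "C")
    k_folds: int = 5
    seed: int = 42
    teacher: TeacherHyper = field(default_factory=TeacherHyper)
    student: StudentConfig = field(default_factory=StudentConfig)
    epsilon: float = 0.005
    k_grid: list[int] | None = None
    out_dir: str = "alscreen_run"

    def validate(self) -> None:
        bad = [d for d in self.definitions if d not in DEFINITIONS]
        if bad:
            raise PipelineError(
                f"unknown target definition(s) {bad}; valid: {list(DEFINITIONS)}"
            )
        if self.k_folds < 2:
            raise PipelineError("k_folds must be at least 2")
        if self.epsilon < 0:
            raise PipelineError("epsilon must be nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["definitions"] = list(self.definitions)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("cohort"), dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        if isinstance(d.get("teacher"), dict):
            d["teacher"] = TeacherHyper(**d["teacher"])
        if isinstance(d.get("student"), dict):
            d["student"] = StudentConfig(**d["student"])
        if "definitions" in d:
            d["definitions"] = tuple(d["definitions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def make_joint_fold_plan(Y: np.ndarray, k: int, seed: int) -> FoldPlan:
    """One stratified plan for all three domains of a definition.

    Stratifies on the joint label pattern across domains; patterns with
    fewer members than folds are pooled into one bucket.
    """
    Y = np.asarray(Y, dtype=int)
    strat = (Y * (2 ** np.arange(Y.shape[1]))).sum(axis=1)
    # fold any stratum smaller than k into the largest stratum
    while True:
        vals, counts = np.unique(strat, return_counts=True)
        small = vals[counts < k]
        if len(small) == 0 or len(vals) <= 1:
            break
        strat = np.where(np.isin(strat, small), vals[np.argmax(counts)], strat)
    if len(np.unique(strat)) < 2:
        strat = Y[:, 0]
    return make_fold_plan(strat, k=k, seed=seed)


def _default_k_grid(p: int) -> list[int]:
    top = min(100, p)
    grid = list(range(5, top + 1, 5))
    return grid or [min(p, 5)]


@dataclass
class DefinitionResult:
    definition: str
    plan: FoldPlan
    targets_m2: dict
    targets_m3: dict
    teachers_full: dict
    rankings: dict[str, list[str]]
    curve: object
    k_star: int
    pruned_features: list[str]
    teachers_pruned: dict
    oof: dict[str, dict[str, np.ndarray]]  # model -> domain -> scores
    metrics: pd.DataFrame


def _cross_domain_ranking(teachers: dict, k: int | None = None) -> list[str]:
    """Merge per-domain importance profiles into one ranking.

    Each domain's mean fold importance is normalized to sum to one before
    averaging, so no domain dominates by scale.
    """
    parts = []
    for res in teachers.values():
        m = res.fold_importances.mean(axis=0)
        total = m.sum()
        parts.append(m / total if total > 0 else m)
    combined = pd.concat(parts, axis=1).mean(axis=1)
    order = sorted(combined.index, key=lambda name: (-combined[name], name))
    return order if k is None else order[:k]


def _interleave_rankings(rankings: dict[str, list[str]], k: int) -> list[str]:
    """Round-robin merge of per-domain rankings into one k-feature set.

    The multi-head student consumes a single feature set; interleaving
    guarantees every domain contributes its strongest predictors.
    """
    out: list[str] = []
    seen: set[str] = set()
    depth = 0
    max_depth = max(len(r) for r in rankings.values())
    while len(out) < k and depth < max_depth:
        for ranked in rankings.values():
            if depth < len(ranked) and ranked[depth] not in seen:
                seen.add(ranked[depth])
                out.append(ranked[depth])
                if len(out) == k:
                    break
        depth += 1
    return out


def _run_definition(
    definition: str,
    cohort: Cohort,
    features: list[str],
    config: RunConfig,
) -> DefinitionResult:
    thresholds = default_thresholds()
    targets_m2 = build_targets(cohort, definition, "M2", thresholds)
    targets_m3 = build_targets(cohort, definition, "M3", thresholds)
    y2 = {d: targets_m2[d].labels.to_numpy() for d in cohort.domain_spec}
    y3 = {d: targets_m3[d].labels.to_numpy() for d in cohort.domain_spec}
    Y3 = np.column_stack([y3[d] for d in cohort.domain_spec])

    plan = make_joint_fold_plan(Y3, k=config.k_folds, seed=config.seed)
    X2 = cohort.X_M2[features]
    X3 = cohort.X_M3[features]

    t0 = time.perf_counter()
    teachers_full = {
        d: fit_teacher(X2, X3, y2[d], y3[d], plan, config.teacher)
        for d in cohort.domain_spec
    }
    logger.info("[%s] teachers (full, p=%d): %.1fs", definition, len(features), time.perf_counter() - t0)

    rankings = {d: aggregate_ranking(t.fold_importances) for d, t in teachers_full.items()}

    k_grid = config.k_grid or _default_k_grid(len(features))
    t0 = time.perf_counter()
    curve = sweep_parsimony(
        rankings, X2, X3, y2, y3, {d: plan for d in cohort.domain_spec},
        k_grid, epsilon=config.epsilon, hyper=config.teacher, definition=definition,
    )
    logger.info("[%s] parsimony sweep (%d grid points): %.1fs", definition, len(k_grid), time.perf_counter() - t0)
    k_star = curve.k_star

    # per-domain models keep their own domain's top-K* features; the
    # multi-head student gets one interleaved K*-feature set
    domain_sets = {
        d: [f for f in features if f in set(rankings[d][:k_star])]
        for d in cohort.domain_spec
    }
    pruned = _interleave_rankings(rankings, k_star)
    X3p = X3[pruned]

    teachers_pruned = {
        d: fit_teacher(
            X2[domain_sets[d]], X3[domain_sets[d]], y2[d], y3[d], plan,
            config.teacher,
        )
        for d in cohort.domain_spec
    }

    teacher_oof = np.column_stack(
        [teachers_pruned[d].oof_outcome for d in cohort.domain_spec]
    )
    distilled = train_student(X3p, Y3, teacher_oof, plan, config.student)
    direct_cfg = StudentConfig(
        **{**asdict(config.student), "lambda_mix": 1.0}
    )
    direct = train_student(X3p, Y3, None, plan, direct_cfg)

    oof: dict[str, dict[str, np.ndarray]] = {m: {} for m in
        ("rf_m3", "logit_l2", "elastic_net", "mlp_direct", "mlp_distill", "teacher")}
    for j, d in enumerate(cohort.domain_spec):
        base = fit_baselines(X3[domain_sets[d]], y3[d], plan, config.teacher, include_mlp=False)
        for m, s in base.items():
            oof[m][d] = s
        oof["mlp_direct"][d] = direct.oof_probs[:, j]
        oof["mlp_distill"][d] = distilled.oof_probs[:, j]
        oof["teacher"][d] = teachers_pruned[d].oof_outcome

    rows = []
    for m, per_domain in oof.items():
        for d, scores in per_domain.items():
            y = y3[d]
            ap = average_precision(scores, y)
            prev = float(y.mean())
            rows.append(
                {"definition": definition, "model": m, "domain": d,
                 "auc": auc(scores, y), "ap": ap, "prevalence": prev,
                 "ap_lift": ap_lift(ap, prev)}
            )
    metrics = pd.DataFrame(rows)

    return DefinitionResult(
        definition=definition, plan=plan, targets_m2=targets_m2,
        targets_m3=targets_m3, teachers_full=teachers_full, rankings=rankings,
        curve=curve, k_star=k_star, pruned_features=pruned,
        teachers_pruned=teachers_pruned, oof=oof, metrics=metrics,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the cohort, per-definition results, and the paths
    of the written tables.  Deterministic under identical configuration.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self
            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    raise PipelineError(
                        f"stage {name!r} failed (config {config.digest()}): {exc}"
                    ) from exc
        return _Stage()

    with stage("cohort"):
        if isinstance(config.cohort, (str, Path)):
            cohort = read_cohort(config.cohort)
        else:
            cohort = generate_cohort(config.cohort)

    with stage("filter"):
        filt = apply_filters(cohort.X_M2, cohort.X_M3, FilterConfig())
        features = filt.eligible
        filt.audit.to_csv(out_dir / "filter_audit.csv")

    results: dict[str, DefinitionResult] = {}
    for definition in config.definitions:
        with stage(f"definition_{definition}"):
            results[definition] = _run_definition(definition, cohort, features, config)

    with stage("report"):
        counts = pd.DataFrame(
            {
                deff: {d: res.targets_m3[d].n_positive for d in cohort.domain_spec}
                for deff, res in results.items()
            }
        ).T
        counts.index.name = "definition"
        counts.to_csv(out_dir / "positive_counts.csv")

        fv_rows = []
        for deff, res in results.items():
            for d in cohort.domain_spec:
                y = res.targets_m3[d].labels.to_numpy()
                for tag, teachers in (("FULL", res.teachers_full), ("K*", res.teachers_pruned)):
                    s = teachers[d].oof_outcome
                    fv_rows.append(
                        {"definition": deff, "predictors": tag, "domain": d,
                         "auc": auc(s, y), "ap": average_precision(s, y)}
                    )
        pd.DataFrame(fv_rows).to_csv(out_dir / "full_vs_kstar.csv", index=False)

        menu = pd.concat([res.metrics for res in results.values()], ignore_index=True)
        menu.to_csv(out_dir / "model_menu.csv", index=False)

        lift = menu[menu["model"] == "mlp_distill"][
            ["definition", "domain", "prevalence", "ap", "ap_lift"]
        ]
        lift.to_csv(out_dir / "ap_lift.csv", index=False)

        curves = pd.concat(
            [res.curve.to_frame().assign(definition=deff) for deff, res in results.items()],
            ignore_index=True,
        )
        curves.to_csv(out_dir / "parsimony_curve.csv", index=False)

        manifest = {
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "n_individuals": cohort.n,
            "n_features_eligible": len(features),
            "k_star": {deff: res.k_star for deff, res in results.items()},
            "pruned_features": {deff: res.pruned_features for deff, res in results.items()},
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {"cohort": cohort, "results": results, "out_dir": out_dir, "manifest": manifest}
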