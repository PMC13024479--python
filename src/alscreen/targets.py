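"""Biomarker-derived dysregulation targets.

Three canonical allostatic-load constructions of the binary high-risk label
for each physiological domain, computed independently at each wave:

* **Q** (quantile): per biomarker, flag the cohort-relative upper quartile
  (lower quartile for protective markers); label = majority of flags.
* **Z** (z-score): standardize each biomarker within wave, sign-reverse
  protective markers, average into a composite, and flag the upper quartile
  of the composite.
* **C** (clinical): per-biomarker flags from externally fixed clinical
  cutoffs (sex-specific where guidelines are), then the same majority rule.

Empirical quantiles use the linear-interpolation convention throughout, and
threshold comparisons are inclusive.  Individuals with any missing biomarker
in a domain are excluded from that domain's labels via ``valid_mask``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFINITIONS = ("Q", "Z", "C")


class TargetError(ValueError):
    """Target construction failed (degenerate column, missing metadata)."""


@dataclass
class TargetLabels:
    """Per-domain risk indicators, composite score, and binary labels."""

    definition: str
    domain: str
    wave: str
    indicators: pd.DataFrame | None  # n x |B_d| binary (None for Z)
    zscores: pd.DataFrame | None     # n x |B_d| signed z-scores (Z only)
    standardization: pd.DataFrame | None  # per-biomarker mean/sd (Z only)
    composite: pd.Series
    labels: pd.Series                # {0,1}, NaN-free on valid rows
    valid_mask: pd.Series            # complete-case per domain

    @property
    def prevalence(self) -> float:
        lab = self.labels[self.valid_mask]
        return float(lab.mean())

    @property
    def n_positive(self) -> int:
        return int(self.labels[self.valid_mask].sum())


def _check_columns(panel: pd.DataFrame) -> pd.Series:
    """Complete-case mask; error on columns too short to take quartiles of."""
    if len(panel) < 4:
        raise TargetError(
            f"biomarker panel has {len(panel)} rows; at least 4 required"
        )
    return ~panel.isna().any(axis=1)


def quantile_indicators(panel: pd.DataFrame, directions: dict[str, int]) -> pd.DataFrame:
    """Cohort-relative quartile risk flags per biomarker.

    Risk-increasing markers flag values >= the empirical 0.75 quantile;
    protective markers flag values <= the 0.25 quantile.  Constant columns
    yield all-zero flags with a warning (flagging the whole cohort is not
    meaningful).
    """
    valid = _check_columns(panel)
    out = pd.DataFrame(0, index=panel.index, columns=panel.columns, dtype=int)
    for col in panel.columns:
        direction = directions[col]
        vals = panel.loc[valid, col].to_numpy(dtype=float)
        if np.nanmax(vals) == np.nanmin(vals):
            warnings.warn(
                f"biomarker {col!r} is constant; emitting all-zero indicators",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        if direction > 0:
            cut = np.quantile(vals, 0.75)
            out.loc[valid, col] = (vals >= cut).astype(int)
        else:
            cut = np.quantile(vals, 0.25)
            out.loc[valid, col] = (vals <= cut).astype(int)
    return out


def score_and_label_majority(indicators: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Composite = row sum of flags; label = 1 iff composite >= |B_d| / 2."""
    arr = indicators.to_numpy()
    if not np.isin(arr[~np.isnan(arr.astype(float))], (0, 1)).all():
        raise TargetError("indicators must be binary")
    composite = indicators.sum(axis=1)
    labels = (composite >= indicators.shape[1] / 2).astype(int)
    return composite, labels


def quantile_labels(
    panel: pd.DataFrame, directions: dict[str, int], *, domain: str = "", wave: str = ""
) -> TargetLabels:
    """The quantile-based (Q) target for one domain at one wave."""
    valid = _check_columns(panel)
    ind = quantile_indicators(panel, directions)
    composite, labels = score_and_label_majority(ind)
    return TargetLabels(
        definition="Q", domain=domain, wave=wave,
        indicators=ind, zscores=None, standardization=None,
        composite=composite, labels=labels.where(valid, 0).astype(int),
        valid_mask=valid,
    )


def zscore_labels(
    panel: pd.DataFrame, directions: dict[str, int], *, domain: str = "", wave: str = ""
) -> TargetLabels:
    """The z-score (Z) target: signed standardized composite, upper-quartile cut.

    Protective biomarkers are sign-reversed after standardization so that
    larger composites always mean greater dysregulation.  The binary label
    flags composites >= the empirical 0.75 quantile of the composite; on an
    entirely tied composite this flags everyone (inclusive comparison) with
    a degeneracy warning.
    """
    valid = _check_columns(panel)
    sub = panel.loc[valid]
    mu = sub.mean()
    sd = sub.std(ddof=1)
    zero_sd = sd[sd == 0]
    if len(zero_sd):
        raise TargetError(
            f"biomarker(s) {list(zero_sd.index)} have zero standard deviation; "
            "standardization undefined"
        )
    z = (sub - mu) / sd
    sign = pd.Series({c: float(directions[c]) for c in panel.columns})
    z = z * sign
    composite_valid = z.mean(axis=1)
    cut = np.quantile(composite_valid.to_numpy(), 0.75)
    if composite_valid.nunique() == 1:
        warnings.warn(
            "degenerate z-score composite: all values tied at the threshold; "
            "every individual is flagged",
            RuntimeWarning,
            stacklevel=2,
        )
    at_cut = (composite_valid == cut).mean()
    if at_cut > 0.30:
        warnings.warn(
            f"{at_cut:.0%} of the cohort sits exactly at the composite "
            "threshold; labels may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    labels_valid = (composite_valid >= cut).astype(int)
    composite = composite_valid.reindex(panel.index)
    labels = labels_valid.reindex(panel.index).fillna(0).astype(int)
    stand = pd.DataFrame({"mean": mu, "sd": sd})
    return TargetLabels(
        definition="Z", domain=domain, wave=wave,
        indicators=None, zscores=z.reindex(panel.index),
        standardization=stand, composite=composite, labels=labels,
        valid_mask=valid,
    )


# --- clinical thresholds --------------------------------------------------

@dataclass(frozen=True)
class ThresholdRule:
    """One biomarker's high-risk criterion.

    ``comparator`` is one of ``>``, ``>=``, ``<``, ``<=`` with a fixed
    ``cutoff`` (possibly sex-specific), or ``upper-quartile`` /
    ``lower-quartile`` for cohort-relative sex-stratified rules.
    """

    domain: str
    biomarker: str
    comparator: str
    cutoff: float | None = None
    cutoff_male: float | None = None
    cutoff_female: float | None = None
    units: str = ""

    @property
    def sex_specific(self) -> bool:
        return self.cutoff_male is not None or self.comparator.endswith("quartile")


@dataclass
class ClinicalThresholdTable:
    """Clinical reference cutoffs for the clinically thresholded (C) target."""

    rules: dict[str, ThresholdRule] = field(default_factory=dict)

    def rule(self, biomarker: str) -> ThresholdRule:
        if biomarker not in self.rules:
            raise TargetError(f"no clinical threshold defined for {biomarker!r}")
        return self.rules[biomarker]


def default_thresholds() -> ClinicalThresholdTable:
    """Standard clinical reference ranges for the eleven panel biomarkers.

    Fixed guideline cutoffs for the inflammatory and metabolic markers;
    cohort-relative sex-stratified quartile rules for the neuroendocrine
    markers, which have no consensus clinical reference range.
    """
    rules = [
        ThresholdRule("INFL", "CRP", ">", 3.0, units="mg/L"),
        ThresholdRule("INFL", "IL6", ">", 3.19, units="pg/mL"),
        ThresholdRule("INFL", "FGN", ">", 400.0, units="mg/dL"),
        ThresholdRule("META", "GLU", ">=", 126.0, units="mg/dL"),
        ThresholdRule("META", "TG", ">=", 150.0, units="mg/dL"),
        ThresholdRule("META", "HDL", "<", cutoff_male=40.0, cutoff_female=50.0, units="mg/dL"),
        ThresholdRule("META", "SBP", ">=", 140.0, units="mmHg"),
        ThresholdRule("META", "DBP", ">=", 90.0, units="mmHg"),
        ThresholdRule("META", "WC", ">", cutoff_male=102.0, cutoff_female=88.0, units="cm"),
        ThresholdRule("NEURO", "COR", "upper-quartile", units="ug/dL"),
        ThresholdRule("NEURO", "DHEA", "lower-quartile", units="ug/dL"),
    ]
    return ClinicalThresholdTable({r.biomarker: r for r in rules})


_CMP = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
}


def _fixed_cut(rule: ThresholdRule, sex: pd.Series) -> np.ndarray:
    if rule.cutoff is not None:
        return np.full(len(sex), rule.cutoff)
    if rule.cutoff_male is None or rule.cutoff_female is None:
        raise TargetError(f"threshold for {rule.biomarker!r} lacks a cutoff")
    return np.where(sex.to_numpy() == "male", rule.cutoff_male, rule.cutoff_female)


def clinical_labels(
    panel: pd.DataFrame,
    thresholds: ClinicalThresholdTable,
    sex: pd.Series | None = None,
    *,
    domain: str = "",
    wave: str = "",
) -> TargetLabels:
    """The clinically thresholded (C) target for one domain at one wave.

    Sex-stratified quartile rules compute the quartile within each sex of
    the complete-case cohort.  Missing ``sex`` with any sex-specific rule is
    an error.
    """
    valid = _check_columns(panel)
    ind = pd.DataFrame(0, index=panel.index, columns=panel.columns, dtype=int)
    for col in panel.columns:
        rule = thresholds.rule(col)
        vals = panel.loc[valid, col].to_numpy(dtype=float)
        if rule.sex_specific and sex is None:
            raise TargetError(
                f"threshold for {col!r} is sex-specific but no sex vector given"
            )
        if rule.comparator in _CMP:
            cuts = _fixed_cut(rule, sex.loc[valid]) if rule.sex_specific else np.full(len(vals), rule.cutoff)
            ind.loc[valid, col] = _CMP[rule.comparator](vals, cuts).astype(int)
        elif rule.comparator in ("upper-quartile", "lower-quartile"):
            sx = sex.loc[valid].to_numpy()
            flags = np.zeros(len(vals), dtype=int)
            for level in np.unique(sx):
                m = sx == level
                if rule.comparator == "upper-quartile":
                    flags[m] = (vals[m] >= np.quantile(vals[m], 0.75)).astype(int)
                else:
                    flags[m] = (vals[m] <= np.quantile(vals[m], 0.25)).astype(int)
            ind.loc[valid, col] = flags
        else:
            raise TargetError(
                f"unknown comparator {rule.comparator!r} for {col!r}"
            )
    composite, labels = score_and_label_majority(ind)
    return TargetLabels(
        definition="C", domain=domain, wave=wave,
        indicators=ind, zscores=None, standardization=None,
        composite=composite, labels=labels.where(valid, 0).astype(int),
        valid_mask=valid,
    )


def build_targets(cohort, definition: str, wave: str,
                  thresholds: ClinicalThresholdTable | None = None) -> dict[str, TargetLabels]:
    """Compute one definition's labels for every domain at one wave."""
    if definition not in DEFINITIONS:
        raise TargetError(
            f"unknown target definition {definition!r}; expected one of {DEFINITIONS}"
        )
    out = {}
    for domain, directions in cohort.domain_spec.items():
        panel = cohort.biomarkers[wave][domain]
        if definition == "Q":
            out[domain] = quantile_labels(panel, directions, domain=domain, wave=wave)
        elif definition == "Z":
            out[domain] = zscore_labels(panel, directions, domain=domain, wave=wave)
        else:
            out[domain] = clinical_labels(
                panel, thresholds or default_thresholds(), cohort.sex,
                domain=domain, wave=wave,
            )
    return out
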