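"""Deterministic predictor-eligibility filtering.

Builds the analytic predictor universe from the raw two-wave survey matrix
by applying, in order: cross-wave availability, categorical name-pattern
exclusions (biomarker-derived variables, administrative/linkage fields,
sampling weights, process metadata), variant collapsing (alias columns fold
into a canonical column), and a usability check (at least one observed value
and nonzero variance after numeric coercion, at both waves).  Every dropped
feature is recorded with the first rule that removed it, so the audit trail
partitions the input exactly into eligible + dropped.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field

import pandas as pd


class FilterConfigError(ValueError):
    pass


@dataclass
class FilterConfig:
    """Name-pattern exclusion rules plus a variant-collapse map.

    ``exclusions`` maps a category name (e.g. ``"biomarker_derived"``) to a
    list of glob patterns; categories are applied in insertion order.
    ``collapse`` maps alias feature names to canonical ones (aliases are
    dropped in favour of their canonical column).
    """

    exclusions: dict[str, list[str]] = field(default_factory=dict)
    collapse: dict[str, str] = field(default_factory=dict)
    require_cross_wave: bool = True

    def validate(self) -> None:
        # canonical targets must not themselves be aliases (acyclic, depth 1)
        for alias, canonical in self.collapse.items():
            if alias == canonical or canonical in self.collapse:
                raise FilterConfigError(
                    f"variant-collapse map is cyclic or chained at {alias!r} -> {canonical!r}"
                )


@dataclass
class FilterResult:
    eligible: list[str]
    audit: pd.DataFrame  # index = feature, columns = kept (bool), reason (str)

    @property
    def dropped(self) -> pd.DataFrame:
        return self.audit[~self.audit["kept"]]


def _coerce_numeric(col: pd.Series) -> pd.Series:
    """Parse-to-real; non-parsable entries become missing."""
    return pd.to_numeric(col, errors="coerce")


def apply_filters(
    X_M2: pd.DataFrame,
    X_M3: pd.DataFrame,
    config: FilterConfig | None = None,
) -> FilterResult:
    """Apply the eligibility rules and return the surviving feature list.

    Idempotent: re-filtering an already-filtered matrix drops nothing.
    """
    config = config or FilterConfig()
    config.validate()

    all_names = list(dict.fromkeys(list(X_M2.columns) + list(X_M3.columns)))
    reason: dict[str, str] = {}

    def drop(name: str, why: str) -> None:
        reason.setdefault(name, why)

    if config.require_cross_wave:
        for name in all_names:
            if name not in X_M2.columns or name not in X_M3.columns:
                drop(name, "cross-wave availability")

    for category, patterns in config.exclusions.items():
        for name in all_names:
            if name in reason:
                continue
            if any(fnmatch.fnmatch(name, pat) for pat in patterns):
                drop(name, category)

    for alias, canonical in config.collapse.items():
        if alias in all_names and alias not in reason:
            if canonical in all_names and canonical not in reason:
                drop(alias, f"variant collapsed into {canonical}")
            # alias with no surviving canonical counterpart is kept as-is

    for name in all_names:
        if name in reason:
            continue
        for wave_name, X in (("M2", X_M2), ("M3", X_M3)):
            vals = _coerce_numeric(X[name])
            observed = vals.dropna()
            if observed.empty:
                drop(name, f"no observed values ({wave_name})")
                break
            if observed.nunique() == 1:
                drop(name, f"zero variance ({wave_name})")
                break

    eligible = [n for n in all_names if n not in reason]
    audit = pd.DataFrame(
        {
            "kept": [n not in reason for n in all_names],
            "reason": [reason.get(n, "") for n in all_names],
        },
        index=pd.Index(all_names, name="feature"),
    )
    return FilterResult(eligible=eligible, audit=audit)


def example_filter_config() -> FilterConfig:
    """A fixture config exercising every exclusion category.

    Real survey dictionaries ship their own pattern lists; this default
    covers the canonical categories with simple glob patterns.
    """
    return FilterConfig(
        exclusions={
            "biomarker-derived": ["bio_*", "al_component_*"],
            "administrative/linkage": ["id_*", "link_*"],
            "sampling weights": ["weight_*", "*_wgt"],
            "process metadata": ["proc_*", "interview_date*"],
        },
        collapse={},
    )
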