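"""Synthetic two-wave cohort generator.

Emulates the data structure of a longitudinal psychometric screening study:
a baseline wave (M2) and a follow-up wave (M3) of survey predictors for the
same individuals, plus panels of physiological biomarkers grouped into three
domains (inflammatory, metabolic, neuroendocrine) measured at both waves.

The generative model is a latent-factor model.  Each individual carries one
latent dysregulation factor per physiological domain.  Baseline factors are
standard normal; follow-up factors are an AR(1)-style mixture of the baseline
factor and fresh innovation, so ``wave_autocorrelation`` controls how much
baseline survey data can know about follow-up physiology.  Informative
predictors are noisy linear readouts of the factors (with a small
cross-loading between domains), redundant predictors are noisy copies of
informative ones, and the remaining predictors are pure noise.  Every
idiosyncratic predictor component persists across waves with the same
autocorrelation, giving the whole predictor matrix realistic cross-wave
correlation.  Biomarkers are linear in their domain's factor with the sign
dictated by the direction flag (protective markers decrease with
dysregulation), placed on clinical measurement scales so threshold-based
labelling is exercised, including sex-shifted means for waist circumference,
HDL, cortisol and DHEA-S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

WAVES = ("M2", "M3")

#: Domain -> biomarker -> direction (+1 risk-increasing, -1 protective).
DOMAIN_SPEC: dict[str, dict[str, int]] = {
    "INFL": {"CRP": +1, "IL6": +1, "FGN": +1},
    "META": {"GLU": +1, "TG": +1, "HDL": -1, "SBP": +1, "DBP": +1, "WC": +1},
    "NEURO": {"COR": +1, "DHEA": -1},
}

# Measurement scale per biomarker: (mean, sd, additive shift for males).
# Chosen so the clinical cutoffs fall inside the bulk of the distribution
# and sex-specific rules are exercised.
_BIOMARKER_SCALE: dict[str, tuple[float, float, float]] = {
    "CRP": (2.6, 1.4, 0.0),     # mg/L, cutoff > 3.0
    "IL6": (2.8, 1.1, 0.0),     # pg/mL, cutoff > 3.19
    "FGN": (340.0, 80.0, 0.0),  # mg/dL, cutoff > 400
    "GLU": (100.0, 25.0, 0.0),  # mg/dL, cutoff >= 126
    "TG": (120.0, 60.0, 0.0),   # mg/dL, cutoff >= 150
    "HDL": (60.0, 14.0, -10.0), # mg/dL, cutoff < 40 (men) / < 50 (women)
    "SBP": (125.0, 18.0, 0.0),  # mmHg, cutoff >= 140
    "DBP": (78.0, 12.0, 0.0),   # mmHg, cutoff >= 90
    "WC": (90.0, 14.0, 10.0),   # cm, cutoff > 102 (men) / > 88 (women)
    "COR": (16.0, 7.0, 2.0),    # ug/dL, sex-specific upper quartile
    "DHEA": (120.0, 50.0, 30.0),  # ug/dL, sex-specific lower quartile
}

_FACTORS = tuple(DOMAIN_SPEC)  # one latent factor per domain
_CROSS_LOADING = 0.3
# psychometric predictors are scale scores (item aggregates), so their
# measurement noise is modest relative to the latent trait
_PREDICTOR_NOISE_SD = 0.6
_REDUNDANT_NOISE_SD = 0.5


class CohortConfigError(ValueError):
    """A cohort configuration violates its invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic two-wave cohort.

    ``effect_size`` scales the latent-factor loading of every biomarker
    relative to its noise; at 0 the biomarkers (hence all labels) carry no
    signal about the predictors.  ``wave_autocorrelation`` is the correlation
    between baseline and follow-up values of every latent component.
    """

    n_individuals: int = 584
    n_predictors: int = 120
    n_informative: int = 12
    n_redundant_per_informative: int = 2
    wave_autocorrelation: float = 0.7
    effect_size: float = 1.5
    biomarker_noise_sd: float = 1.0
    missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise CohortConfigError("n_individuals must be positive")
        if self.n_predictors <= 0:
            raise CohortConfigError("n_predictors must be positive")
        if self.n_informative < 0:
            raise CohortConfigError("n_informative must be nonnegative")
        if self.n_redundant_per_informative < 0:
            raise CohortConfigError("n_redundant_per_informative must be nonnegative")
        n_struct = self.n_informative * (1 + self.n_redundant_per_informative)
        if n_struct > self.n_predictors:
            raise CohortConfigError(
                "n_informative + n_informative * n_redundant_per_informative "
                f"= {n_struct} exceeds n_predictors = {self.n_predictors}"
            )
        if not 0.0 <= self.wave_autocorrelation <= 1.0:
            raise CohortConfigError("wave_autocorrelation must lie in [0, 1]")
        if self.effect_size < 0:
            raise CohortConfigError("effect_size must be nonnegative")
        if self.biomarker_noise_sd <= 0:
            raise CohortConfigError("biomarker_noise_sd must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise CohortConfigError("missing_rate must lie in [0, 1)")


@dataclass
class Cohort:
    """A generated (or loaded) two-wave cohort.

    ``X`` maps wave -> n x p predictor DataFrame (identical columns at both
    waves); ``biomarkers`` maps wave -> domain -> n x |B_d| DataFrame;
    ``sex`` is a length-n Series of {"male", "female"}.
    """

    X: dict[str, pd.DataFrame]
    biomarkers: dict[str, dict[str, pd.DataFrame]]
    sex: pd.Series
    feature_meta: pd.DataFrame
    domain_spec: dict[str, dict[str, int]]
    config: CohortConfig | None = None

    @property
    def n(self) -> int:
        return len(self.sex)

    @property
    def X_M2(self) -> pd.DataFrame:
        return self.X["M2"]

    @property
    def X_M3(self) -> pd.DataFrame:
        return self.X["M3"]

    def informative_features(self) -> list[str]:
        meta = self.feature_meta
        return list(meta.index[meta["role"] == "informative"])

    def noise_features(self) -> list[str]:
        meta = self.feature_meta
        return list(meta.index[meta["role"] == "noise"])

    def validate(self) -> None:
        if self.n == 0:
            raise CohortFormatError("empty cohort: no individuals")
        if list(self.X["M2"].columns) != list(self.X["M3"].columns):
            raise CohortFormatError("predictor columns differ between waves")
        for domain, markers in self.domain_spec.items():
            for wave in WAVES:
                cols = list(self.biomarkers[wave][domain].columns)
                if cols != list(markers):
                    raise CohortFormatError(
                        f"biomarker set of domain {domain} at wave {wave} "
                        f"({cols}) does not match the domain spec ({list(markers)})"
                    )


class CohortFormatError(ValueError):
    """A cohort on disk (or in memory) is structurally invalid."""


def _ar1_pair(rng: np.random.Generator, shape: tuple[int, ...], rho: float):
    """Draw a unit-variance pair (e_M2, e_M3) with corr(e_M2, e_M3) = rho."""
    base = rng.standard_normal(shape)
    innov = rng.standard_normal(shape)
    return base, rho * base + math.sqrt(max(0.0, 1.0 - rho * rho)) * innov


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a two-wave cohort under the latent-factor model.

    Deterministic: an identical config (including seed) yields a
    bit-identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_individuals, config.n_predictors
    rho = config.wave_autocorrelation

    sex = pd.Series(
        np.where(rng.random(n) < 0.5, "male", "female"), name="sex"
    )
    male = (sex == "male").to_numpy(dtype=float)

    # Latent dysregulation factors, one per domain.
    f2, f3 = _ar1_pair(rng, (n, len(_FACTORS)), rho)
    factors = {"M2": f2, "M3": f3}

    # --- predictors -------------------------------------------------------
    names: list[str] = []
    roles: list[str] = []
    factor_of: list[int] = []
    group_of: list[int] = []
    cols = {"M2": [], "M3": []}

    def _add(name, role, fac, grp, col2, col3):
        names.append(name)
        roles.append(role)
        factor_of.append(fac)
        group_of.append(grp)
        cols["M2"].append(col2)
        cols["M3"].append(col3)

    informative_cols = {}
    for i in range(config.n_informative):
        fac = i % len(_FACTORS)
        other = (fac + 1) % len(_FACTORS)
        e2, e3 = _ar1_pair(rng, (n,), rho)
        col2 = f2[:, fac] + _CROSS_LOADING * f2[:, other] + _PREDICTOR_NOISE_SD * e2
        col3 = f3[:, fac] + _CROSS_LOADING * f3[:, other] + _PREDICTOR_NOISE_SD * e3
        name = f"inf{i:03d}"
        informative_cols[i] = (col2, col3)
        _add(name, "informative", fac, i, col2, col3)

    for i in range(config.n_informative):
        for j in range(config.n_redundant_per_informative):
            e2, e3 = _ar1_pair(rng, (n,), rho)
            p2, p3 = informative_cols[i]
            _add(
                f"red{i:03d}_{j}",
                "redundant",
                i % len(_FACTORS),
                i,
                p2 + _REDUNDANT_NOISE_SD * e2,
                p3 + _REDUNDANT_NOISE_SD * e3,
            )

    n_noise = p - len(names)
    for i in range(n_noise):
        e2, e3 = _ar1_pair(rng, (n,), rho)
        _add(f"noise{i:03d}", "noise", -1, -1, e2, e3)

    X = {
        w: pd.DataFrame(np.column_stack(cols[w]), columns=names)
        for w in WAVES
    }

    if config.missing_rate > 0:
        for w in WAVES:
            mask = rng.random((n, p)) < config.missing_rate
            vals = X[w].to_numpy()
            vals[mask] = np.nan
            X[w] = pd.DataFrame(vals, columns=names)

    feature_meta = pd.DataFrame(
        {"role": roles, "factor": factor_of, "group": group_of}, index=pd.Index(names, name="feature")
    )

    # --- biomarkers -------------------------------------------------------
    e = config.effect_size
    denom = math.sqrt(e * e + config.biomarker_noise_sd**2)
    biomarkers: dict[str, dict[str, pd.DataFrame]] = {w: {} for w in WAVES}
    for d_idx, (domain, markers) in enumerate(DOMAIN_SPEC.items()):
        marker_cols = {w: {} for w in WAVES}
        for marker, direction in markers.items():
            mu, sd, male_shift = _BIOMARKER_SCALE[marker]
            for w in WAVES:
                eps = rng.standard_normal(n)
                u = (direction * e * factors[w][:, d_idx] + config.biomarker_noise_sd * eps) / denom
                marker_cols[w][marker] = mu + male_shift * male + sd * u
        for w in WAVES:
            biomarkers[w][domain] = pd.DataFrame(marker_cols[w])

    cohort = Cohort(
        X=X,
        biomarkers=biomarkers,
        sex=sex,
        feature_meta=feature_meta,
        domain_spec={d: dict(m) for d, m in DOMAIN_SPEC.items()},
        config=config,
    )
    cohort.validate()
    return cohort


# --- persistence ----------------------------------------------------------

def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as delimited tables plus a YAML metadata sidecar."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for w in WAVES:
        cohort.X[w].to_csv(path / f"predictors_{w.lower()}.csv", index=False)
        panel = pd.concat(
            [cohort.biomarkers[w][d] for d in cohort.domain_spec], axis=1
        )
        panel.to_csv(path / f"biomarkers_{w.lower()}.csv", index=False)
    pd.DataFrame({"sex": cohort.sex}).to_csv(path / "subjects.csv", index=False)
    cohort.feature_meta.to_csv(path / "feature_meta.csv")
    sidecar = {
        "waves": list(WAVES),
        "sex_column": "sex",
        "domains": {
            d: {m: ("risk" if s > 0 else "protective") for m, s in markers.items()}
            for d, markers in cohort.domain_spec.items()
        },
    }
    if cohort.config is not None:
        sidecar["config"] = {
            k: (float(v) if isinstance(v, float) else v)
            for k, v in vars(cohort.config).items()
        }
    (path / "cohort.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_cohort(path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`, validating structure."""
    from pathlib import Path

    path = Path(path)
    sidecar_path = path / "cohort.yaml"
    if not sidecar_path.exists():
        raise CohortFormatError(f"missing metadata sidecar {sidecar_path}")
    sidecar = yaml.safe_load(sidecar_path.read_text())
    if not isinstance(sidecar, dict) or "domains" not in sidecar:
        raise CohortFormatError("malformed sidecar: no 'domains' section")

    domain_spec: dict[str, dict[str, int]] = {}
    for domain, markers in sidecar["domains"].items():
        domain_spec[domain] = {}
        for marker, flag in markers.items():
            if flag not in ("risk", "protective"):
                raise CohortFormatError(
                    f"biomarker {marker!r} in domain {domain!r} has invalid "
                    f"or missing direction flag {flag!r}"
                )
            domain_spec[domain][marker] = 1 if flag == "risk" else -1

    X = {w: pd.read_csv(path / f"predictors_{w.lower()}.csv") for w in WAVES}
    panels = {w: pd.read_csv(path / f"biomarkers_{w.lower()}.csv") for w in WAVES}
    biomarkers: dict[str, dict[str, pd.DataFrame]] = {w: {} for w in WAVES}
    for w in WAVES:
        for domain, markers in domain_spec.items():
            missing = [m for m in markers if m not in panels[w].columns]
            if missing:
                raise CohortFormatError(
                    f"biomarker(s) {missing} of domain {domain} absent at wave {w}"
                )
            biomarkers[w][domain] = panels[w][list(markers)].copy()

    subjects = pd.read_csv(path / "subjects.csv")
    sex_col = sidecar.get("sex_column", "sex")
    if sex_col not in subjects.columns:
        raise CohortFormatError(f"subjects table lacks sex column {sex_col!r}")
    sex = subjects[sex_col].astype(str).rename("sex")

    meta_path = path / "feature_meta.csv"
    if meta_path.exists():
        feature_meta = pd.read_csv(meta_path, index_col="feature")
    else:
        feature_meta = pd.DataFrame(
            {"role": "unknown", "factor": -1, "group": -1},
            index=pd.Index(X["M2"].columns, name="feature"),
        )

    config = None
    if "config" in sidecar:
        try:
            config = CohortConfig(**sidecar["config"])
        except TypeError:
            config = None

    cohort = Cohort(
        X=X,
        biomarkers=biomarkers,
        sex=sex,
        feature_meta=feature_meta,
        domain_spec=domain_spec,
        config=config,
    )
    cohort.validate()
    return cohort
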