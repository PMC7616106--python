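"""Configuration for the synthetic cohort generator and the analysis pipeline.

All knobs of the generator live here: the two-subtype z-score progression
structure behind the lobar CT scores, the linear lung-function decline model,
centre effects, and the decline-dependent Weibull survival process.  Values
are chosen to emulate a multi-centre IPF cohort; see ``docs/methods.md`` for
the rationale behind each default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError
from .grouping import BIOMARKER_COLS, EMPHYSEMA_COLS, FIBROSIS_COLS


@dataclass
class PFTParams:
    """Baseline pulmonary function, true decline slopes and visit schedule.

    Slopes are relative (% of baseline per year, negative = decline); the
    FVC and DLco slopes of a subject are drawn jointly with correlation
    ``slope_correlation``.  Measurement noise is Gaussian with SD expressed
    as a percentage of the subject's baseline value.  ``fvc_noise_sd_pct_high_emphysema``
    optionally inflates FVC noise for subjects with lung emphysema at or
    above ``high_emphysema_threshold`` — the mechanism by which extensive
    emphysema superimposes heterogeneity on expiratory volumes.
    """

    fvc_baseline_mean_ml: float = 2800.0
    fvc_baseline_sd_ml: float = 600.0
    dlco_baseline_mean: float = 15.0  # ml/min/mmHg
    dlco_baseline_sd: float = 4.0
    fvc_pp_mean: float = 80.0
    fvc_pp_sd: float = 20.0
    dlco_pp_mean: float = 50.0
    dlco_pp_sd: float = 15.0
    fev1_fvc_mean: float = 0.80
    fev1_fvc_sd: float = 0.07
    # decline spread calibrated to the reported threshold proportions
    # (roughly half of IPF patients cross the 5%/10% relative-decline marks)
    fvc_rel_slope_mean: float = -5.0
    fvc_rel_slope_sd: float = 8.0
    dlco_rel_slope_mean: float = -8.0
    dlco_rel_slope_sd: float = 8.0
    slope_correlation: float = 0.7
    noise_sd_pct: float = 3.0
    fvc_noise_sd_pct_high_emphysema: float | None = None
    high_emphysema_threshold: float = 10.0
    visit_months: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0)
    visit_jitter_sd_days: float = 10.0
    baseline_jitter_sd_days: float = 20.0
    missing_prob: float = 0.15

    def validate(self) -> None:
        for name in (
            "fvc_baseline_sd_ml",
            "dlco_baseline_sd",
            "fvc_pp_sd",
            "dlco_pp_sd",
            "fev1_fvc_sd",
            "fvc_rel_slope_sd",
            "dlco_rel_slope_sd",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"pft_params.{name} must be > 0")
        if self.noise_sd_pct < 0:
            raise ConfigurationError("pft_params.noise_sd_pct must be >= 0")
        if not -1.0 <= self.slope_correlation <= 1.0:
            raise ConfigurationError("pft_params.slope_correlation must be in [-1, 1]")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ConfigurationError("pft_params.missing_prob must be in [0, 1)")
        if len(self.visit_months) < 1 or self.visit_months[0] != 0.0:
            raise ConfigurationError("pft_params.visit_months must start at 0")


@dataclass
class SurvivalParams:
    """Weibull proportional-hazards generator for time to death.

    The linear predictor is sum_j coef_j * (x_j - center_j) plus a Gaussian
    centre intercept; event times follow a Weibull with the given scale
    (years) and shape, censored administratively at ``censor_years``.
    Decline covariates (``fvc_rel_decline_true`` / ``dlco_rel_decline_true``)
    are the true 1-year relative declines in percent (positive = worsening),
    so a coefficient of 0.03 means a hazard ratio of about 1.03 per 1% of
    annual decline — the scale the Cox models report.
    """

    weibull_scale_years: float = 6.0
    weibull_shape: float = 1.3
    coefficients: dict = field(
        default_factory=lambda: {
            "age": 0.03,
            "male": 0.2,
            "smoking_ever": 0.15,
            "antifibrotic_ever": -0.2,
            "dlco_pp_baseline": -0.03,
            "fvc_rel_decline_true": 0.03,
            "dlco_rel_decline_true": 0.03,
        }
    )
    centers: dict = field(
        default_factory=lambda: {"age": 65.0, "dlco_pp_baseline": 50.0}
    )
    centre_sd: float = 0.3
    censor_years: float = 5.0

    def validate(self) -> None:
        if self.weibull_scale_years <= 0 or self.weibull_shape <= 0:
            raise ConfigurationError("survival_params Weibull parameters must be > 0")
        if self.centre_sd < 0:
            raise ConfigurationError("survival_params.centre_sd must be >= 0")
        if self.censor_years < 0:
            raise ConfigurationError("survival_params.censor_years must be >= 0")
        for k, v in self.coefficients.items():
            if not np.isfinite(v):
                raise ConfigurationError(f"survival_params.coefficients[{k}] not finite")


@dataclass
class CovariateParams:
    """Demographics and their link to generated emphysema extent.

    Smoking probability follows a logistic link in lung emphysema percentage
    (ever-smokers are more frequent at higher emphysema extents); baseline
    percent-predicted DLco decreases linearly with emphysema extent.
    """

    age_mean: float = 68.0
    age_sd: float = 9.0
    male_prob: float = 0.8
    smoking_intercept: float = 0.0
    smoking_slope_per_pct: float = 0.15
    antifibrotic_prob: float = 0.5
    dlco_pp_emphysema_slope: float = -0.5

    def validate(self) -> None:
        if self.age_sd <= 0:
            raise ConfigurationError("covariate_params.age_sd must be > 0")
        for name in ("male_prob", "antifibrotic_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"covariate_params.{name} must be in [0, 1]")


def default_biomarker_sd_map() -> dict:
    """Interobserver single-determination SD per biomarker (percent units).

    Fibrosis extents are scored over a wider dynamic range than emphysema,
    so their interobserver SD is larger.
    """
    sd = {c: 10.0 for c in FIBROSIS_COLS}
    sd.update({c: 5.0 for c in EMPHYSEMA_COLS})
    return sd


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort reproducibly."""

    n_subjects: int = 500
    n_centres: int = 3
    #: fraction of the cohort that is non-CPFE IPF: fibrosis progresses but
    #: emphysema is structurally absent (visual score exactly 0 in all lobes)
    non_cpfe_fraction: float = 0.35
    subtype_fractions: tuple[float, ...] = (0.6, 0.4)
    event_orderings: Sequence[Sequence[int]] | None = None
    z_noise_sd: float | Sequence[float] = 1.0
    stage_distribution: str | Sequence[float] = "uniform"
    z_max: float | Sequence[float] = 3.0
    biomarker_sd_map: Mapping[str, float] = field(default_factory=default_biomarker_sd_map)
    pft_params: PFTParams = field(default_factory=PFTParams)
    survival_params: SurvivalParams = field(default_factory=SurvivalParams)
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be >= 0")
        if self.n_centres < 1:
            raise ConfigurationError("n_centres must be >= 1")
        if not 0.0 <= self.non_cpfe_fraction < 1.0:
            raise ConfigurationError("non_cpfe_fraction must be in [0, 1)")
        fr = np.asarray(self.subtype_fractions, dtype=float)
        if fr.ndim != 1 or len(fr) < 1 or (fr < 0).any():
            raise ConfigurationError("subtype_fractions must be non-negative")
        if abs(fr.sum() - 1.0) > 1e-12:
            raise ConfigurationError("subtype_fractions must sum to 1 within 1e-12")
        noise = np.broadcast_to(
            np.asarray(self.z_noise_sd, dtype=float), (len(BIOMARKER_COLS),)
        )
        if (noise < 0).any():
            raise ConfigurationError("z_noise_sd must be >= 0")
        for b in BIOMARKER_COLS:
            if b not in self.biomarker_sd_map:
                raise ConfigurationError(f"biomarker_sd_map missing {b}")
            if self.biomarker_sd_map[b] <= 0:
                raise ConfigurationError(f"biomarker_sd_map[{b}] must be > 0")
        zmax = np.broadcast_to(
            np.asarray(self.z_max, dtype=float), (len(BIOMARKER_COLS),)
        )
        if (zmax < 1).any():
            raise ConfigurationError("z_max must be >= 1 for every biomarker")
        self.pft_params.validate()
        self.survival_params.validate()
        self.covariate_params.validate()
        if not isinstance(self.stage_distribution, str):
            p = np.asarray(self.stage_distribution, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError("stage_distribution must be a probability vector")
        elif self.stage_distribution != "uniform":
            raise ConfigurationError(
                f"unknown stage_distribution: {self.stage_distribution!r}"
            )

    @property
    def n_subtypes(self) -> int:
        return len(self.subtype_fractions)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["biomarker_sd_map"] = dict(self.biomarker_sd_map)
        if self.event_orderings is not None:
            d["event_orderings"] = [list(map(int, o)) for o in self.event_orderings]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        for key, sub in (
            ("pft_params", PFTParams),
            ("survival_params", SurvivalParams),
            ("covariate_params", CovariateParams),
        ):
            if key in d and isinstance(d[key], Mapping):
                kwargs = dict(d[key])
                if "visit_months" in kwargs:
                    kwargs["visit_months"] = tuple(kwargs["visit_months"])
                d[key] = sub(**kwargs)
        if "subtype_fractions" in d:
            d["subtype_fractions"] = tuple(d["subtype_fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert numpy scalars/arrays and tuples for YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    return obj
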