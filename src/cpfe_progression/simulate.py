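"""Synthetic CPFE cohorts with known ground truth.

The generator reproduces the statistical structure the analysis assumes:
lobar fibrosis/emphysema extents arise from a two-subtype z-score progression
model (a subject sits at a stage along their subtype's event ordering and the
expected z-trajectory is mapped back to extent percent through the
interobserver SD); lung function declines linearly per subject; mortality
follows a Weibull proportional-hazards model whose linear predictor includes
the true declines and a Gaussian centre intercept.  A truth table aligned by
subject id supports parameter-recovery tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import CohortConfig, SurvivalParams
from .errors import ConfigurationError, GenerationError
from .grouping import BIOMARKER_COLS, EMPHYSEMA_COLS, FIBROSIS_COLS
from .sustain import ZScoreMatrix, is_valid_ordering, trajectory_matrix

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = (
    ["subject_id", "centre_id", "age", "male", "smoking_ever", "antifibrotic_ever"]
    + ["fvc_pp_baseline", "dlco_pp_baseline", "fev1_fvc_ratio"]
    + list(BIOMARKER_COLS)
    + ["lung_fibrosis_pct", "lung_emphysema_pct", "survival_years", "death"]
)
PFT_COLUMNS = ["subject_id", "measure", "days", "value", "centre_id"]
TRUTH_COLUMNS = [
    "subject_id",
    "subtype",
    "stage",
    "fvc_rel_decline_true",
    "dlco_rel_decline_true",
    "fvc_slope_ml_per_yr",
    "dlco_slope_per_yr",
    "hazard_lp",
    "centre_intercept",
]

_LOWER_FIRST = ("right_lower", "left_lower", "right_middle", "lingula", "right_upper", "left_upper")
_UPPER_FIRST = ("right_upper", "left_upper", "right_middle", "lingula", "right_lower", "left_lower")


def generator_zmatrix(config: CohortConfig) -> ZScoreMatrix:
    """Empty z-matrix carrying the generator's event grids (for trajectories)."""
    zmax = np.broadcast_to(
        np.asarray(config.z_max, dtype=float), (len(BIOMARKER_COLS),)
    )
    grids = tuple(np.arange(1.0, m + 0.5) for m in zmax)
    return ZScoreMatrix(
        np.zeros((0, len(BIOMARKER_COLS))), BIOMARKER_COLS, grids, zmax
    )


def _event_index(biomarker: str, z: int, zm: ZScoreMatrix) -> int:
    b = zm.biomarkers.index(biomarker)
    start = int(np.sum([len(g) for g in zm.event_grids[:b]]))
    return start + (z - 1)


def default_event_orderings(config: CohortConfig) -> list[np.ndarray]:
    """Canonical generating orderings for the two CPFE subtypes.

    Subtype 0 (*fibrosis-dominant*): all fibrosis events (lower lobes first)
    run ahead; emphysema emerges late.  Subtype 1 (*matched*): fibrosis and
    emphysema worsen together, with emphysema relatively more extensive at
    late stages.  Both respect within-biomarker grid order by construction.
    """
    zm = generator_zmatrix(config)
    zmax = int(round(float(np.max(zm.z_max))))

    def ev(kind: str, lobes: tuple[str, ...], z: int) -> list[int]:
        return [_event_index(f"{kind}_{lobe}", z, zm) for lobe in lobes]

    fib_dom: list[int] = []
    for z in range(1, zmax + 1):
        fib_dom += ev("fibrosis", _LOWER_FIRST, z)
    for z in range(1, zmax + 1):
        fib_dom += ev("emphysema", _UPPER_FIRST, z)

    matched: list[int] = []
    matched += ev("fibrosis", _LOWER_FIRST, 1)
    matched += ev("emphysema", _UPPER_FIRST, 1)
    for z in range(2, zmax + 1):
        matched += ev("emphysema", _UPPER_FIRST, z)
        matched += ev("fibrosis", _LOWER_FIRST, z)
    out = [np.array(fib_dom), np.array(matched)]
    return out[: config.n_subtypes] + [
        np.array(fib_dom) for _ in range(max(0, config.n_subtypes - 2))
    ]


def well_separated_orderings(config: CohortConfig) -> list[np.ndarray]:
    """Two maximally distinct generating orderings (reversed lobar progressions).

    Subtype 0 accumulates all fibrosis events (lower lobes first) before any
    emphysema; subtype 1 accumulates all emphysema events (upper lobes first)
    before any fibrosis, with the within-process lobe order reversed relative
    to subtype 0.  Used by parameter-recovery studies where the subtypes must
    be identifiable from mid-trajectory data.
    """
    zm = generator_zmatrix(config)
    zmax = int(round(float(np.max(zm.z_max))))

    def ev(kind: str, lobes: tuple[str, ...], z: int) -> list[int]:
        return [_event_index(f"{kind}_{lobe}", z, zm) for lobe in lobes]

    first: list[int] = []
    for z in range(1, zmax + 1):
        first += ev("fibrosis", _LOWER_FIRST, z)
    for z in range(1, zmax + 1):
        first += ev("emphysema", _UPPER_FIRST, z)
    second: list[int] = []
    for z in range(1, zmax + 1):
        second += ev("emphysema", _LOWER_FIRST, z)
    for z in range(1, zmax + 1):
        second += ev("fibrosis", _UPPER_FIRST, z)
    return [np.array(first), np.array(second)]


def _empty_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    return (
        pd.DataFrame(columns=PATIENT_COLUMNS),
        pd.DataFrame(columns=PFT_COLUMNS),
        pd.DataFrame(columns=TRUTH_COLUMNS),
    )


def simulate_survival(
    covariates: pd.DataFrame,
    params: SurvivalParams,
    rng: np.random.Generator | int | None,
    centre_intercepts: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weibull proportional-hazards event times with administrative censoring.

    ``covariates`` must contain every column named in ``params.coefficients``;
    the linear predictor is sum_j coef_j * (x_j - center_j) plus the per-row
    centre intercept.  Returns (time in years, event flag).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(covariates)
    lp = np.zeros(n)
    for name, coef in params.coefficients.items():
        if name not in covariates.columns:
            raise ConfigurationError(f"covariate table missing column {name}")
        lp += coef * (
            covariates[name].to_numpy(dtype=float) - params.centers.get(name, 0.0)
        )
    if centre_intercepts is not None:
        lp += np.asarray(centre_intercepts, dtype=float)
    if not np.all(np.isfinite(lp)):
        bad = covariates.index[~np.isfinite(lp)].tolist()
        sid = (
            covariates.loc[bad, "subject_id"].tolist()
            if "subject_id" in covariates.columns
            else bad
        )
        raise GenerationError(f"non-finite hazard linear predictor for subjects {sid}")
    if n == 0:
        return np.array([]), np.array([], dtype=int)
    # S(t) = exp(-(t/scale)^shape * e^lp)  =>  T = scale * (E / e^lp)^(1/shape)
    e = rng.exponential(size=n)
    t_event = params.weibull_scale_years * (e / np.exp(lp)) ** (1.0 / params.weibull_shape)
    time = np.minimum(t_event, params.censor_years)
    event = (t_event <= params.censor_years).astype(int)
    return time, event


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patient table, PFT series table, truth table).

    Fully reproducible for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    if n == 0:
        return _empty_tables()

    zm = generator_zmatrix(config)
    orderings = (
        [np.asarray(o, dtype=int) for o in config.event_orderings]
        if config.event_orderings is not None
        else default_event_orderings(config)
    )
    if len(orderings) != config.n_subtypes:
        raise ConfigurationError("event_orderings: need one ordering per subtype")
    for i, o in enumerate(orderings):
        if not is_valid_ordering(zm, o):
            raise ConfigurationError(
                f"event_orderings[{i}] is not a valid permutation of the event set"
            )
    trajectories = [trajectory_matrix(zm, o) for o in orderings]
    N = zm.n_events

    subject_id = np.array([f"S{i:05d}" for i in range(n)])
    centre_idx = rng.integers(config.n_centres, size=n)
    centre_id = np.array([f"C{c + 1}" for c in centre_idx])
    centre_effects = rng.normal(0.0, config.survival_params.centre_sd, config.n_centres)
    centre_intercept = centre_effects[centre_idx]

    subtype = rng.choice(config.n_subtypes, size=n, p=np.asarray(config.subtype_fractions))
    if isinstance(config.stage_distribution, str):
        stage = rng.integers(0, N + 1, size=n)
    else:
        stage = rng.choice(len(np.asarray(config.stage_distribution)), size=n,
                           p=np.asarray(config.stage_distribution))

    # non-CPFE IPF component: fibrosis progresses along the first subtype's
    # ordering, emphysema is structurally absent (subtype index -1 in truth)
    non_cpfe = rng.random(n) < config.non_cpfe_fraction
    emph_idx = [BIOMARKER_COLS.index(c) for c in EMPHYSEMA_COLS]
    if non_cpfe.any():
        # stage capped before the first emphysema event of the reference ordering
        is_emph_event = np.isin(zm.event_biomarker[orderings[0]], emph_idx)
        first_emph_pos = (
            int(np.nonzero(is_emph_event)[0][0] + 1) if is_emph_event.any() else N + 1
        )
        if isinstance(config.stage_distribution, str):
            nc_stage = rng.integers(0, first_emph_pos, size=n)
        else:  # explicit stage law: keep it, clipped to the fibrosis-only range
            nc_stage = np.minimum(stage, first_emph_pos - 1)
        stage = np.where(non_cpfe, nc_stage, stage)
        subtype = np.where(non_cpfe, 0, subtype)

    sd_vec = np.array([config.biomarker_sd_map[b] for b in BIOMARKER_COLS])
    noise_sd = np.broadcast_to(
        np.asarray(config.z_noise_sd, dtype=float), (len(BIOMARKER_COLS),)
    )
    z_traj = np.stack([trajectories[s][k] for s, k in zip(subtype, stage)])
    extents = z_traj * sd_vec + rng.normal(0.0, 1.0, (n, len(BIOMARKER_COLS))) * (
        noise_sd * sd_vec
    )
    extents = np.clip(extents, 0.0, 100.0)
    if non_cpfe.any():
        extents[np.ix_(non_cpfe, emph_idx)] = 0.0
        subtype = np.where(non_cpfe, -1, subtype)

    panels = pd.DataFrame(extents, columns=list(BIOMARKER_COLS))
    lung_fib = panels[list(FIBROSIS_COLS)].mean(axis=1).to_numpy()
    lung_emph = panels[list(EMPHYSEMA_COLS)].mean(axis=1).to_numpy()

    cov = config.covariate_params
    age = rng.normal(cov.age_mean, cov.age_sd, n)
    male = rng.binomial(1, cov.male_prob, n)
    p_smoke = expit(cov.smoking_intercept + cov.smoking_slope_per_pct * lung_emph)
    smoking = rng.binomial(1, p_smoke)
    antifibrotic = rng.binomial(1, cov.antifibrotic_prob, n)

    pft = config.pft_params
    fvc_pp = np.clip(rng.normal(pft.fvc_pp_mean, pft.fvc_pp_sd, n), 20.0, 150.0)
    dlco_pp = np.clip(
        rng.normal(pft.dlco_pp_mean, pft.dlco_pp_sd, n)
        + cov.dlco_pp_emphysema_slope * lung_emph,
        10.0,
        150.0,
    )
    fev1_fvc = np.clip(rng.normal(pft.fev1_fvc_mean, pft.fev1_fvc_sd, n), 0.4, 1.2)

    fvc_baseline = np.clip(
        rng.normal(pft.fvc_baseline_mean_ml, pft.fvc_baseline_sd_ml, n), 800.0, None
    )
    dlco_baseline = np.clip(
        rng.normal(pft.dlco_baseline_mean, pft.dlco_baseline_sd, n), 2.0, None
    )
    # joint draw of relative slopes (% of baseline per year, negative = decline)
    corr = pft.slope_correlation
    cov_mat = np.array(
        [
            [pft.fvc_rel_slope_sd**2, corr * pft.fvc_rel_slope_sd * pft.dlco_rel_slope_sd],
            [corr * pft.fvc_rel_slope_sd * pft.dlco_rel_slope_sd, pft.dlco_rel_slope_sd**2],
        ]
    )
    slopes = rng.multivariate_normal(
        [pft.fvc_rel_slope_mean, pft.dlco_rel_slope_mean], cov_mat, size=n
    )
    fvc_slope_rel, dlco_slope_rel = slopes[:, 0], slopes[:, 1]
    fvc_decline = -fvc_slope_rel  # positive = worsening, the Cox covariate scale
    dlco_decline = -dlco_slope_rel

    # longitudinal series
    high_emph = lung_emph >= pft.high_emphysema_threshold
    if pft.fvc_noise_sd_pct_high_emphysema is None:
        fvc_noise_pct = np.full(n, pft.noise_sd_pct)
    else:
        fvc_noise_pct = np.where(
            high_emph, pft.fvc_noise_sd_pct_high_emphysema, pft.noise_sd_pct
        )
    rows: list[tuple] = []
    months = np.asarray(pft.visit_months, dtype=float)
    for i in range(n):
        base_day = float(
            np.clip(rng.normal(0.0, pft.baseline_jitter_sd_days), -85.0, 85.0)
        )
        days = months * 30.4375 + rng.normal(0.0, pft.visit_jitter_sd_days, len(months))
        days[0] = base_day
        days[1:] = np.maximum(days[1:], base_day + 14.0)
        keep = np.ones(len(months), dtype=bool)
        keep[1:] = rng.random(len(months) - 1) >= pft.missing_prob
        for measure, baseline, slope_rel, noise_pct in (
            ("fvc", fvc_baseline[i], fvc_slope_rel[i], fvc_noise_pct[i]),
            ("dlco", dlco_baseline[i], dlco_slope_rel[i], pft.noise_sd_pct),
        ):
            noise = rng.normal(0.0, noise_pct / 100.0 * baseline, len(months))
            for j in range(len(months)):
                if not keep[j]:
                    continue
                t_years = days[j] / 365.25
                value = baseline * (1.0 + slope_rel / 100.0 * t_years) + noise[j]
                value = max(value, 0.02 * baseline)
                rows.append((subject_id[i], measure, days[j], value, centre_id[i]))
    pft_series = pd.DataFrame(rows, columns=PFT_COLUMNS)

    cov_table = pd.DataFrame(
        {
            "subject_id": subject_id,
            "age": age,
            "male": male,
            "smoking_ever": smoking,
            "antifibrotic_ever": antifibrotic,
            "dlco_pp_baseline": dlco_pp,
            "fvc_rel_decline_true": fvc_decline,
            "dlco_rel_decline_true": dlco_decline,
        }
    )
    surv_time, event = simulate_survival(
        cov_table, config.survival_params, rng, centre_intercept
    )
    lp = np.zeros(n)
    for name, coef in config.survival_params.coefficients.items():
        lp += coef * (
            cov_table[name].to_numpy(dtype=float)
            - config.survival_params.centers.get(name, 0.0)
        )
    lp += centre_intercept

    patients = pd.DataFrame({"subject_id": subject_id, "centre_id": centre_id})
    patients["age"] = age
    patients["male"] = male
    patients["smoking_ever"] = smoking
    patients["antifibrotic_ever"] = antifibrotic
    patients["fvc_pp_baseline"] = fvc_pp
    patients["dlco_pp_baseline"] = dlco_pp
    patients["fev1_fvc_ratio"] = fev1_fvc
    for c in BIOMARKER_COLS:
        patients[c] = panels[c].to_numpy()
    patients["lung_fibrosis_pct"] = lung_fib
    patients["lung_emphysema_pct"] = lung_emph
    patients["survival_years"] = surv_time
    patients["death"] = event

    truth = pd.DataFrame(
        {
            "subject_id": subject_id,
            "subtype": subtype,
            "stage": stage,
            "fvc_rel_decline_true": fvc_decline,
            "dlco_rel_decline_true": dlco_decline,
            "fvc_slope_ml_per_yr": fvc_baseline * fvc_slope_rel / 100.0,
            "dlco_slope_per_yr": dlco_baseline * dlco_slope_rel / 100.0,
            "hazard_lp": lp,
            "centre_intercept": centre_intercept,
        }
    )
    logger.info(
        "generated cohort: n=%d, centres=%d, events=%d",
        n,
        config.n_centres,
        int(event.sum()),
    )
    return patients, pft_series, truth


def generate_dual_reads(
    panels: pd.DataFrame,
    read_noise_sd: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two independent noisy reads of each lobar extent, clamped to [0, 100].

    Emulates the dual-radiologist scoring subset used to estimate
    interobserver variability.  Returns a long table
    (subject_id, biomarker, read1, read2).
    """
    if read_noise_sd < 0:
        raise ConfigurationError("read_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if len(panels) == 0:
        return pd.DataFrame(columns=["subject_id", "biomarker", "read1", "read2"])
    ids = (
        panels["subject_id"].to_numpy()
        if "subject_id" in panels.columns
        else np.arange(len(panels))
    )
    records = []
    truth = panels.loc[:, list(BIOMARKER_COLS)].to_numpy(dtype=float)
    noise = rng.normal(0.0, read_noise_sd, size=(2,) + truth.shape)
    r1 = np.clip(truth + noise[0], 0.0, 100.0)
    r2 = np.clip(truth + noise[1], 0.0, 100.0)
    for j, b in enumerate(BIOMARKER_COLS):
        for i in range(len(panels)):
            records.append((ids[i], b, r1[i, j], r2[i, j]))
    return pd.DataFrame(records, columns=["subject_id", "biomarker", "read1", "read2"])
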