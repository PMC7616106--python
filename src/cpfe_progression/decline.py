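"""Per-subject 1-year lung-function decline via linear mixed-effects models.

Eligibility windows: a baseline measurement within 3 months (91 days) of the
baseline CT, at least one later follow-up, and no measurements beyond 18
months (548 days).  The model has fixed effects for age, sex, smoking
history, antifibrotic use, baseline percent-predicted value and time since
baseline CT, and a random intercept and random time slope per subject,
estimated by REML.  Relative decline is 100 minus the subject-specific
(empirical-Bayes) prediction of percent-of-baseline at one year (365.25
days); absolute decline is the drop in raw units over the same year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ValidationError
from .tables import percent

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
BASELINE_WINDOW_DAYS = 91.0
FOLLOWUP_LIMIT_DAYS = 548.0

#: inclusive relative-decline thresholds per measure (percent at 1 year)
DECLINE_THRESHOLDS = {"fvc": (5.0, 10.0), "dlco": (10.0, 15.0)}
BASELINE_PP_COL = {"fvc": "fvc_pp_baseline", "dlco": "dlco_pp_baseline"}

ADJUSTER_COLS = ("age", "male", "smoking_ever", "antifibrotic_ever")


def prepare_series(
    pft: pd.DataFrame, measure: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the eligibility windows to a long PFT table.

    Keeps subjects with a baseline measurement within ±91 days of the CT
    (nearest to the CT date, earlier on ties) and at least one later
    measurement; drops rows after 548 days, rows before the baseline
    measurement, and same-day duplicates (first kept).  Returns the eligible
    series (with ``baseline_day``/``baseline_value`` columns) and an
    exclusion log.
    """
    df = pft[pft["measure"] == measure].copy()
    df = df.sort_values(["subject_id", "days"], kind="stable")
    dup = df.duplicated(subset=["subject_id", "days"], keep="first")
    if dup.any():
        logger.info("%d duplicate same-day %s measurements dropped", dup.sum(), measure)
        df = df[~dup]
    empty = pd.DataFrame(columns=list(df.columns) + ["baseline_day", "baseline_value"])
    if df.empty:
        return empty, pd.DataFrame(columns=["subject_id", "reason"])

    # baseline = in-window measurement nearest the CT date, earlier on ties
    in_window = df[df["days"].abs() <= BASELINE_WINDOW_DAYS]
    base = (
        in_window.assign(absday=in_window["days"].abs())
        .sort_values(["subject_id", "absday", "days"], kind="stable")
        .groupby("subject_id", sort=False)
        .first()[["days", "value"]]
        .rename(columns={"days": "baseline_day", "value": "baseline_value"})
    )
    no_baseline = sorted(set(df["subject_id"]) - set(base.index))

    merged = df.merge(base, left_on="subject_id", right_index=True, how="inner")
    merged = merged[
        (merged["days"] >= merged["baseline_day"])
        & (merged["days"] <= FOLLOWUP_LIMIT_DAYS)
    ]
    has_followup = (
        merged[merged["days"] > merged["baseline_day"]].groupby("subject_id").size()
    )
    no_followup = sorted(set(base.index) - set(has_followup.index))
    eligible = merged[merged["subject_id"].isin(has_followup.index)].reset_index(
        drop=True
    )
    log = pd.DataFrame(
        [(s, "no baseline measurement within 91 days of CT") for s in no_baseline]
        + [(s, "no follow-up measurement after baseline") for s in no_followup],
        columns=["subject_id", "reason"],
    )
    if len(log):
        logger.info("%s eligibility excluded %d subjects", measure, len(log))
    if eligible.empty:
        return empty, log
    return eligible, log


def to_percent_of_baseline(series: pd.DataFrame) -> pd.DataFrame:
    """Divide each measurement by the subject's baseline and multiply by 100."""
    if (series["baseline_value"] <= 0).any():
        bad = series.loc[series["baseline_value"] <= 0, "subject_id"].unique().tolist()
        raise ValidationError(f"non-positive baseline value for subjects {bad}")
    out = series.copy()
    out["value"] = 100.0 * out["value"] / out["baseline_value"]
    return out


@dataclass
class PartitionFit:
    """One fitted mixed model plus the subject-level empirical-Bayes summaries."""

    result: object
    fe_names: list[str]
    subjects: pd.DataFrame  # subject_id, fixed_at_zero, slope_per_year
    diagonal_refit: bool = False
    dropped_covariates: list[str] = field(default_factory=list)


@dataclass
class DeclineFit:
    measure: str
    scale: str  # "percent" or "raw"
    partition_col: str | None
    partitions: dict[str, PartitionFit]

    def subject_table(self) -> pd.DataFrame:
        return pd.concat(
            [p.subjects for p in self.partitions.values()], ignore_index=True
        )


def _fit_one_partition(data: pd.DataFrame, fe_cols: list[str]) -> PartitionFit:
    dropped = [c for c in fe_cols if data[c].nunique() <= 1]
    if dropped:
        logger.warning("dropping constant covariates: %s", dropped)
    use = [c for c in fe_cols if c not in dropped]
    exog = sm.add_constant(data[use + ["time_years"]], has_constant="add")
    exog_re = pd.DataFrame(
        {"re_intercept": np.ones(len(data)), "re_time": data["time_years"]},
        index=data.index,
    )
    model = sm.MixedLM(
        data["value"].to_numpy(dtype=float),
        exog,
        groups=data["subject_id"].to_numpy(),
        exog_re=exog_re,
    )
    diagonal = False
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        # variance components on the boundary (noiseless or near-degenerate
        # inputs) trigger routine optimiser warnings; diagnostics are kept in
        # the returned fit instead
        _warnings.simplefilter("ignore", ConvergenceWarning)
        _warnings.simplefilter("ignore", UserWarning)
        _warnings.simplefilter("ignore", RuntimeWarning)
        result = model.fit(reml=True, method="lbfgs")
        if not result.converged:
            # optimiser failure (as opposed to a legitimate boundary/singular
            # solution): retry with the intercept-slope correlation pinned to
            # zero, which removes the worst-conditioned direction
            free = MixedLMParams.from_components(
                fe_params=np.ones(exog.shape[1]), cov_re=np.eye(2)
            )
            result = model.fit(reml=True, free=free, method="lbfgs")
            diagonal = True
    fe = result.fe_params
    re_tab = pd.DataFrame(result.random_effects).T  # index: subject id
    first = data.groupby("subject_id", sort=False).first()
    fixed0 = fe["const"] + sum(fe[c] * first[c] for c in use) if use else pd.Series(
        fe["const"], index=first.index
    )
    subjects = pd.DataFrame(
        {
            "subject_id": first.index,
            "pred_at_zero": (fixed0 + re_tab.loc[first.index, "re_intercept"]).to_numpy(),
            "slope_per_year": (
                fe["time_years"] + re_tab.loc[first.index, "re_time"]
            ).to_numpy(),
        }
    ).reset_index(drop=True)
    subjects["pred_at_one_year"] = (
        subjects["pred_at_zero"] + subjects["slope_per_year"]
    )
    return PartitionFit(result, list(exog.columns), subjects, diagonal, dropped)


def fit_decline_lme(
    series: pd.DataFrame,
    covariates: pd.DataFrame,
    measure: str,
    scale: str = "percent",
    partition_col: str | None = None,
) -> DeclineFit:
    """REML linear mixed model(s) with random intercept and slope per subject.

    ``series`` is the eligible long table from :func:`prepare_series` (already
    percent-of-baseline transformed when ``scale='percent'``); ``covariates``
    is the patient table.  One model is fitted per level of ``partition_col``
    (e.g. centre/country), or a single model when None.
    """
    baseline_pp = BASELINE_PP_COL[measure]
    fe_cols = list(ADJUSTER_COLS) + [baseline_pp]
    merged = series.merge(
        covariates[["subject_id"] + fe_cols], on="subject_id", how="inner"
    )
    missing = merged[fe_cols].isna().any(axis=1)
    if missing.any():
        sids = merged.loc[missing, "subject_id"].nunique()
        logger.info("excluding %d subjects with incomplete covariates", sids)
        merged = merged[~missing]
    merged = merged.copy()
    merged["time_years"] = merged["days"] / DAYS_PER_YEAR
    partitions: dict[str, PartitionFit] = {}
    if partition_col is None:
        groups = [("all", merged)]
    else:
        groups = list(merged.groupby(partition_col, sort=True))
    for label, g in groups:
        n_sub = g["subject_id"].nunique()
        if n_sub < 10:
            logger.warning(
                "partition %s has only %d subjects (floor 10); fitting anyway",
                label,
                n_sub,
            )
        if n_sub < 3:
            logger.warning("partition %s skipped: too few subjects", label)
            continue
        partitions[str(label)] = _fit_one_partition(g, fe_cols)
    return DeclineFit(measure, scale, partition_col, partitions)


@dataclass
class DeclineEstimate:
    subject_id: object
    measure: str
    absolute_decline: float
    relative_decline: float
    flags: dict[float, bool]


def one_year_decline(
    percent_fit: DeclineFit, raw_fit: DeclineFit, subject_id
) -> DeclineEstimate:
    """Subject-specific absolute and relative 1-year decline with flags.

    Relative decline is 100 minus the conditional (fixed + empirical-Bayes)
    prediction of percent-of-baseline at one year; absolute decline is the
    predicted raw-scale drop over the first year.  Threshold flags are
    inclusive (>=).
    """
    tab = one_year_declines(percent_fit, raw_fit)
    row = tab[tab["subject_id"] == subject_id]
    if row.empty:
        raise KeyError(f"subject {subject_id} not present in fitted decline model")
    r = row.iloc[0]
    thresholds = DECLINE_THRESHOLDS[percent_fit.measure]
    return DeclineEstimate(
        subject_id=subject_id,
        measure=percent_fit.measure,
        absolute_decline=float(r["absolute_decline"]),
        relative_decline=float(r["relative_decline"]),
        flags={t: bool(r[f"decline_ge_{t:g}"]) for t in thresholds},
    )


def one_year_declines(percent_fit: DeclineFit, raw_fit: DeclineFit) -> pd.DataFrame:
    """Table of per-subject 1-year decline estimates for one measure."""
    if percent_fit.scale != "percent" or raw_fit.scale != "raw":
        raise ValidationError("expected a percent-scale and a raw-scale fit")
    pct = percent_fit.subject_table()[["subject_id", "pred_at_one_year"]]
    raw = raw_fit.subject_table()[["subject_id", "slope_per_year"]]
    tab = pct.merge(raw, on="subject_id", how="inner")
    tab["relative_decline"] = 100.0 - tab["pred_at_one_year"]
    tab["absolute_decline"] = -tab["slope_per_year"]
    tab["measure"] = percent_fit.measure
    # flags use the decline at the tables' printed precision (2 decimals,
    # round-half-up) so an exact-threshold trajectory is not lost to the
    # optimiser's last 1e-5
    from .tables import round_half_up

    rounded = tab["relative_decline"].map(lambda v: round_half_up(v, 2))
    for t in DECLINE_THRESHOLDS[percent_fit.measure]:
        tab[f"decline_ge_{t:g}"] = rounded >= t
    return tab.drop(columns=["pred_at_one_year", "slope_per_year"])


def estimate_decline(
    pft: pd.DataFrame,
    patients: pd.DataFrame,
    measure: str,
    partition_col: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """prepare -> normalise -> fit both scales -> per-subject estimates.

    Returns the estimates table and the eligibility exclusion log.
    """
    eligible, log = prepare_series(pft, measure)
    if eligible.empty:
        return (
            pd.DataFrame(
                columns=["subject_id", "relative_decline", "absolute_decline", "measure"]
            ),
            log,
        )
    pct = to_percent_of_baseline(eligible)
    fit_pct = fit_decline_lme(pct, patients, measure, "percent", partition_col)
    fit_raw = fit_decline_lme(eligible, patients, measure, "raw", partition_col)
    return one_year_declines(fit_pct, fit_raw), log


@dataclass
class DeclineSummary:
    table: pd.DataFrame
    chi2_tests: pd.DataFrame
    anova_p: float
    tukey: pd.DataFrame | None


def decline_summary(
    estimates: pd.DataFrame,
    group_labels: pd.Series,
    measure: str,
) -> DeclineSummary:
    """Group-level decline table with chi-squared and ANOVA/Tukey tests.

    ``group_labels`` maps every subject in the cohort (indexed by subject_id)
    to a group, so the ``n with data / n total`` column reflects missing
    longitudinal data.  Threshold proportions are compared pairwise with
    chi-squared tests and Bonferroni adjustment over the pairwise
    comparisons; mean absolute decline with one-way ANOVA plus Tukey HSD.
    """
    thresholds = DECLINE_THRESHOLDS[measure]
    est = estimates.merge(
        group_labels.rename("group"), left_on="subject_id", right_index=True, how="left"
    )
    groups = [g for g in group_labels.dropna().unique()]
    if hasattr(group_labels, "cat"):
        groups = [g for g in group_labels.cat.categories if g in set(groups)]
    rows = []
    for g in groups:
        total = int((group_labels == g).sum())
        sub = est[est["group"] == g]
        row = {
            "group": g,
            "n_with_data": len(sub),
            "n_total": total,
            "mean_absolute_decline": sub["absolute_decline"].mean()
            if len(sub)
            else np.nan,
        }
        for t in thresholds:
            k = int(sub[f"decline_ge_{t:g}"].sum()) if len(sub) else 0
            row[f"n_ge_{t:g}"] = k
            row[f"pct_ge_{t:g}"] = percent(k, len(sub), 2) if len(sub) else np.nan
        if len(sub) == 0:
            logger.warning("group %s has no decline estimates; tests skipped", g)
        rows.append(row)
    table = pd.DataFrame(rows)

    pairs = [
        (groups[i], groups[j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    ]
    chi_rows = []
    for t in thresholds:
        for ga, gb in pairs:
            ra = table[table["group"] == ga].iloc[0]
            rb = table[table["group"] == gb].iloc[0]
            tab = np.array(
                [
                    [ra[f"n_ge_{t:g}"], ra["n_with_data"] - ra[f"n_ge_{t:g}"]],
                    [rb[f"n_ge_{t:g}"], rb["n_with_data"] - rb[f"n_ge_{t:g}"]],
                ]
            )
            if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
                p = np.nan
            else:
                p = stats.chi2_contingency(tab).pvalue
            chi_rows.append(
                {
                    "threshold": t,
                    "comparison": f"{ga} vs {gb}",
                    "p_raw": p,
                    "p_bonferroni": min(1.0, p * len(pairs)) if np.isfinite(p) else np.nan,
                }
            )
    chi2_tests = pd.DataFrame(chi_rows)

    samples = [
        est.loc[est["group"] == g, "absolute_decline"].dropna().to_numpy()
        for g in groups
    ]
    valid = [s for s in samples if len(s) >= 2]
    anova_p = float(stats.f_oneway(*valid).pvalue) if len(valid) >= 2 else np.nan
    tukey = None
    if len(valid) >= 2:
        mask = est["group"].notna() & est["absolute_decline"].notna()
        counts = est.loc[mask, "group"].value_counts()
        ok = counts[counts >= 2].index
        sub = est[mask & est["group"].isin(ok)]
        if sub["group"].nunique() >= 2:
            res = pairwise_tukeyhsd(
                sub["absolute_decline"].to_numpy(), sub["group"].astype(str).to_numpy()
            )
            tukey = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
    return DeclineSummary(table, chi2_tests, anova_p, tukey)
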