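"""Lobar scores to lung percentages, CPFE classes and agreement statistics.

Fibrosis and emphysema extent are visually scored as a percentage of each of
six lobes (the lingula counted as the sixth lobe).  The lung percentage of
either process is the arithmetic mean of the six lobar extents.  CPFE is
defined as any visually scored emphysema; CPFE patients are subdivided at a
10% (primary) or 15% (secondary) lung-emphysema threshold, boundary
inclusive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

LOBES = (
    "right_upper",
    "right_middle",
    "right_lower",
    "left_upper",
    "lingula",
    "left_lower",
)

FIBROSIS_COLS = tuple(f"fibrosis_{lobe}" for lobe in LOBES)
EMPHYSEMA_COLS = tuple(f"emphysema_{lobe}" for lobe in LOBES)
#: The 12 biomarkers of the subtype model: 6 lobar fibrosis extents followed
#: by 6 lobar emphysema extents.
BIOMARKER_COLS = FIBROSIS_COLS + EMPHYSEMA_COLS

NON_CPFE = "non-CPFE"
CPFE_BELOW = "CPFE-below-threshold"
CPFE_AT_OR_ABOVE = "CPFE-at-or-above-threshold"
CPFE_CATEGORIES = (NON_CPFE, CPFE_BELOW, CPFE_AT_OR_ABOVE)


@dataclass(frozen=True)
class CpfeLabel:
    category: str
    threshold: float


def lung_percentage(panel: Mapping[str, float]) -> tuple[float, float]:
    """Mean of the six lobar extents for fibrosis and emphysema.

    ``panel`` maps ``fibrosis_<lobe>``/``emphysema_<lobe>`` to extents in
    [0, 100].  Lobar extents are summed and divided by 6 to obtain a lung
    percentage.
    """
    values = {}
    for col in BIOMARKER_COLS:
        if col not in panel or panel[col] is None or (
            isinstance(panel[col], float) and math.isnan(panel[col])
        ):
            raise ValidationError(f"missing lobar extent: {col}")
        v = float(panel[col])
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"extent out of [0, 100] for {col}: {v}")
        values[col] = v
    fib = sum(values[c] for c in FIBROSIS_COLS) / 6.0
    emph = sum(values[c] for c in EMPHYSEMA_COLS) / 6.0
    return fib, emph


def lung_percentages(panels: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`lung_percentage` over a wide lobar-score table."""
    missing = [c for c in BIOMARKER_COLS if c not in panels.columns]
    if missing:
        raise ValidationError(f"missing lobar extent columns: {missing}")
    block = panels.loc[:, list(BIOMARKER_COLS)].astype(float)
    if block.isna().any().any():
        bad = block.columns[block.isna().any()].tolist()
        raise ValidationError(f"missing lobar extents in columns: {bad}")
    if (block.values < 0).any() or (block.values > 100).any():
        raise ValidationError("lobar extents must lie in [0, 100]")
    out = pd.DataFrame(index=panels.index)
    out["lung_fibrosis_pct"] = block[list(FIBROSIS_COLS)].mean(axis=1)
    out["lung_emphysema_pct"] = block[list(EMPHYSEMA_COLS)].mean(axis=1)
    return out


def classify_cpfe(emphysema_pct: float, threshold: float = 10.0) -> CpfeLabel:
    """CPFE class from the lung emphysema percentage.

    0% emphysema is non-CPFE; any emphysema below the threshold is
    CPFE-below-threshold; at or above the threshold (inclusive) is
    CPFE-at-or-above-threshold.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    e = float(emphysema_pct)
    if math.isnan(e) or e < 0:
        raise ValidationError(f"emphysema percentage invalid: {emphysema_pct}")
    if e == 0.0:
        return CpfeLabel(NON_CPFE, threshold)
    if e < threshold:
        return CpfeLabel(CPFE_BELOW, threshold)
    return CpfeLabel(CPFE_AT_OR_ABOVE, threshold)


def classify_cpfe_series(emphysema_pct: pd.Series, threshold: float = 10.0) -> pd.Series:
    """Vectorised CPFE classification; returns a categorical series."""
    labels = [classify_cpfe(e, threshold).category for e in emphysema_pct]
    return pd.Series(
        pd.Categorical(labels, categories=list(CPFE_CATEGORIES)),
        index=emphysema_pct.index,
        name=f"cpfe_class_{threshold:g}",
    )


def trial_eligible(
    dlco_pp: float | None, fvc_pp: float | None, fev1_fvc: float | None
) -> bool:
    """Lung-function eligibility for therapeutic IPF trials.

    Requires percent-predicted DLco > 30, percent-predicted FVC > 50 and
    FEV1/FVC ratio > 0.7 — all strict inequalities.
    """
    fields = {"dlco_pp": dlco_pp, "fvc_pp": fvc_pp, "fev1_fvc": fev1_fvc}
    for name, v in fields.items():
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValidationError(f"trial eligibility indeterminate: missing {name}")
    return dlco_pp > 30.0 and fvc_pp > 50.0 and fev1_fvc > 0.7


def trial_eligibility_flags(patients: pd.DataFrame) -> pd.Series:
    """Per-patient eligibility; indeterminate records become False and are logged."""
    flags = []
    n_missing = 0
    for _, row in patients.iterrows():
        try:
            flags.append(
                trial_eligible(
                    row.get("dlco_pp_baseline"),
                    row.get("fvc_pp_baseline"),
                    row.get("fev1_fvc_ratio"),
                )
            )
        except ValidationError:
            flags.append(False)
            n_missing += 1
    if n_missing:
        logger.info("trial eligibility indeterminate for %d records", n_missing)
    return pd.Series(flags, index=patients.index, name="trial_eligible")


def apply_cohort_filter(
    patients: pd.DataFrame, min_survival_days: float = 91.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude patients who died within 3 months (91 days) of the baseline CT.

    Returns the retained table and a log of exclusions.  Records flagged in an
    optional boolean ``exclude`` column (e.g. infection or cancer on baseline
    CT) are removed as well.
    """
    reasons = pd.Series("", index=patients.index)
    early = (patients["death"].astype(bool)) & (
        patients["survival_years"] * 365.25 < min_survival_days
    )
    reasons[early] = f"died within {min_survival_days:g} days of baseline CT"
    if "exclude" in patients.columns:
        flagged = patients["exclude"].fillna(False).astype(bool)
        reasons[flagged & (reasons == "")] = "flagged for exclusion at baseline"
    dropped = reasons != ""
    log = pd.DataFrame(
        {"subject_id": patients.loc[dropped, "subject_id"], "reason": reasons[dropped]}
    )
    if len(log):
        logger.info("cohort filter excluded %d patients", len(log))
    return patients.loc[~dropped].copy(), log.reset_index(drop=True)


def single_determination_sd(
    pairs: Iterable[tuple[float, float]] | pd.DataFrame,
) -> float:
    """Single determination standard deviation of paired reads.

    For paired reads with differences d_i, returns sqrt(sum(d_i^2) / (2 n)) —
    the interobserver variability used to z-score the lobar extents.
    """
    if isinstance(pairs, pd.DataFrame):
        arr = pairs.iloc[:, :2].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValidationError("single_determination_sd requires at least one pair")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be (read1, read2) tuples")
    d = arr[:, 0] - arr[:, 1]
    return float(np.sqrt(np.sum(d**2) / (2.0 * len(d))))


def cohens_kappa(labels1: Sequence, labels2: Sequence) -> float:
    """Cohen's kappa for two raters' binary (or categorical) labels.

    kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e from the
    product of the raters' marginal frequencies.
    """
    a = np.asarray(labels1)
    b = np.asarray(labels2)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("label vectors must be 1-d and equal length")
    n = len(a)
    if n < 2:
        raise ValidationError("kappa requires at least two paired labels")
    cats = np.unique(np.concatenate([a, b]))
    po = float(np.mean(a == b))
    pe = 0.0
    for c in cats:
        pe += float(np.mean(a == c)) * float(np.mean(b == c))
    if pe >= 1.0 - 1e-15:
        raise ValidationError("kappa undefined: both raters are constant")
    return (po - pe) / (1.0 - pe)


def baseline_comparison(
    patients: pd.DataFrame,
    group_col: str,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Baseline characteristics table with between-group tests.

    Continuous variables are summarised as mean±SD and compared with
    two-sample t-tests; categorical variables as count (%) with chi-squared
    tests.  With a single group no test columns are emitted; with more than
    two groups every pairwise comparison gets its own p-value column.
    Degenerate tests (zero variance, empty cells) are skipped with a logged
    reason and reported as NaN.
    """
    groups = [g for g in patients[group_col].dropna().unique()]
    if len(groups) == 0:
        raise ValidationError("no groups present")
    groups = sorted(groups, key=str)
    pairs = [
        (groups[i], groups[j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    ]
    rows = []
    for var in continuous:
        row: dict = {"variable": var, "type": "continuous"}
        for g in groups:
            vals = patients.loc[patients[group_col] == g, var].dropna()
            row[f"{g}"] = (
                f"{vals.mean():.1f}±{vals.std(ddof=1):.1f} (n={len(vals)})"
                if len(vals) >= 2
                else f"n={len(vals)}"
            )
            row[f"{g}_missing"] = int(patients[group_col].eq(g).sum() - len(vals))
        for ga, gb in pairs:
            va = patients.loc[patients[group_col] == ga, var].dropna()
            vb = patients.loc[patients[group_col] == gb, var].dropna()
            key = f"p[{ga} vs {gb}]" if len(pairs) > 1 else "p"
            if len(va) < 2 or len(vb) < 2 or (va.std() == 0 and vb.std() == 0):
                logger.info("t-test skipped for %s (%s vs %s): degenerate", var, ga, gb)
                row[key] = np.nan
            else:
                row[key] = stats.ttest_ind(va, vb, equal_var=False).pvalue
        rows.append(row)
    for var in categorical:
        row = {"variable": var, "type": "categorical"}
        for g in groups:
            vals = patients.loc[patients[group_col] == g, var].dropna()
            pos = int(pd.Series(vals).astype(bool).sum()) if len(vals) else 0
            row[f"{g}"] = (
                f"{pos}/{len(vals)} ({100 * pos / len(vals):.1f}%)" if len(vals) else "0/0"
            )
            row[f"{g}_missing"] = int(patients[group_col].eq(g).sum() - len(vals))
        for ga, gb in pairs:
            key = f"p[{ga} vs {gb}]" if len(pairs) > 1 else "p"
            sub = patients[patients[group_col].isin([ga, gb])]
            tab = pd.crosstab(sub[group_col].astype(str), sub[var].dropna())
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                logger.info("chi2 skipped for %s (%s vs %s): degenerate", var, ga, gb)
                row[key] = np.nan
            else:
                row[key] = stats.chi2_contingency(tab.values).pvalue
        rows.append(row)
    return pd.DataFrame(rows)
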