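"""End-to-end orchestration: filter -> group -> subtype -> decline -> survival.

``run_analysis`` executes the whole chain on a simulated or user-supplied
cohort and returns a :class:`ReportBundle` of tables mirroring the clinical
report: baseline characteristics, decline summaries per subgroup, Cox results
per subgroup x decline covariate (skipping models failing the
events-per-covariate rule), Kaplan-Meier summaries and the subtype model.
Every run is bitwise reproducible for a fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decline, grouping, survival, sustain
from .config import CohortConfig
from .errors import ConfigurationError, ValidationError
from .simulate import generate_cohort
from .tables import percent

logger = logging.getLogger(__name__)

DECLINE_COVARIATES = (
    ("fvc", "fvc_rel_decline"),
    ("fvc", "fvc_decline_ge_5"),
    ("fvc", "fvc_decline_ge_10"),
    ("dlco", "dlco_rel_decline"),
    ("dlco", "dlco_decline_ge_10"),
    ("dlco", "dlco_decline_ge_15"),
)


@dataclass
class AnalysisConfig:
    """What to analyse and how.

    Exactly one input source: either ``cohort`` (simulate) or both input
    paths (CSV tables with the documented schemas).
    """

    cohort: CohortConfig | None = None
    patients_path: str | None = None
    pft_path: str | None = None
    emphysema_thresholds: tuple[float, ...] = (10.0, 15.0)
    subtype_mode: str = "force-2"  # "force-2" | "select" | "skip"
    sustain_kwargs: dict = field(default_factory=dict)
    trial_subanalysis: bool = False
    lme_partition_col: str | None = None
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        simulated = self.cohort is not None
        loaded = self.patients_path is not None and self.pft_path is not None
        if simulated == loaded:
            raise ConfigurationError(
                "exactly one input source: a CohortConfig or both input paths"
            )
        if any(t <= 0 for t in self.emphysema_thresholds):
            raise ConfigurationError("emphysema thresholds must be positive")
        if self.subtype_mode not in ("force-2", "select", "skip"):
            raise ConfigurationError(f"unknown subtype_mode {self.subtype_mode!r}")


@dataclass
class ReportBundle:
    baseline_table: pd.DataFrame
    cohort_summaries: dict  # threshold -> DataFrame
    decline_estimates: pd.DataFrame
    decline_summaries: dict  # (measure, grouping) -> decline.DeclineSummary
    cox_table: pd.DataFrame
    km_results: dict  # grouping -> survival.KMResult
    subtype_model: sustain.SubtypeModel | None
    subtype_assignments: pd.DataFrame | None
    patients: pd.DataFrame
    exclusion_log: pd.DataFrame
    run_log: dict


def cohort_summary(labels: pd.Series, decimals: int = 0) -> pd.DataFrame:
    """Counts and printed-precision percentages per CPFE class.

    Adds an ``any emphysema (CPFE)`` row pooling the two emphysema classes.
    """
    n = len(labels)
    rows = []
    cats = (
        list(labels.cat.categories)
        if hasattr(labels, "cat")
        else sorted(labels.unique(), key=str)
    )
    for c in cats:
        k = int((labels == c).sum())
        rows.append({"class": c, "n": k, "pct": percent(k, n, decimals) if n else np.nan})
    cpfe = int((labels != grouping.NON_CPFE).sum())
    rows.append(
        {
            "class": "any emphysema (CPFE)",
            "n": cpfe,
            "pct": percent(cpfe, n, decimals) if n else np.nan,
        }
    )
    return pd.DataFrame(rows)


def _decline_wide(pft: pd.DataFrame, patients: pd.DataFrame, partition_col):
    """Per-measure decline estimates pivoted to one row per subject."""
    frames, logs = [], []
    for measure in ("fvc", "dlco"):
        est, log = decline.estimate_decline(pft, patients, measure, partition_col)
        log["stage"] = f"decline eligibility ({measure})"
        logs.append(log)
        if est.empty:
            continue
        renamed = est.rename(
            columns={
                "relative_decline": f"{measure}_rel_decline",
                "absolute_decline": f"{measure}_abs_decline",
                **{
                    f"decline_ge_{t:g}": f"{measure}_decline_ge_{t:g}"
                    for t in decline.DECLINE_THRESHOLDS[measure]
                },
            }
        ).drop(columns=["measure"])
        frames.append(renamed)
    if not frames:
        return pd.DataFrame(columns=["subject_id"]), pd.concat(logs, ignore_index=True)
    wide = frames[0]
    for f in frames[1:]:
        wide = wide.merge(f, on="subject_id", how="outer")
    return wide, pd.concat(logs, ignore_index=True)


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the full analysis; see the module docstring for the stages."""
    rng = np.random.default_rng(config.seed)
    if config.cohort is not None:
        patients, pft, _truth = generate_cohort(config.cohort)
        sd_map = dict(config.cohort.biomarker_sd_map)
    else:
        patients = pd.read_csv(config.patients_path)
        pft = pd.read_csv(config.pft_path)
        missing = [c for c in grouping.BIOMARKER_COLS if c not in patients.columns]
        if missing:
            raise ValidationError(f"patient table missing columns: {missing}")
        from .config import default_biomarker_sd_map

        sd_map = default_biomarker_sd_map()
    patients, excl = grouping.apply_cohort_filter(patients)
    if "lung_emphysema_pct" not in patients.columns:
        patients = patients.join(grouping.lung_percentages(patients))

    summaries = {}
    for thr in config.emphysema_thresholds:
        patients[f"cpfe_class_{thr:g}"] = grouping.classify_cpfe_series(
            patients["lung_emphysema_pct"], thr
        )
        summaries[thr] = cohort_summary(patients[f"cpfe_class_{thr:g}"])
    primary = f"cpfe_class_{config.emphysema_thresholds[0]:g}"

    baseline = grouping.baseline_comparison(
        patients,
        primary,
        continuous=("age", "lung_fibrosis_pct", "lung_emphysema_pct",
                    "fvc_pp_baseline", "dlco_pp_baseline"),
        categorical=("male", "smoking_ever", "antifibrotic_ever"),
    )

    model, assignments = None, None
    if config.subtype_mode != "skip":
        emph_patients = sustain.restrict_to_emphysema(patients, patients)
        if emph_patients.empty:
            logger.warning("no emphysema-positive subjects: subtype stage skipped")
        else:
            zm = sustain.compute_zscores(emph_patients, sd_map)
            kwargs = dict(config.sustain_kwargs)
            if config.subtype_mode == "select":
                candidates = kwargs.pop("candidates", (1, 2, 3))
                chosen, cv_table = sustain.select_n_subtypes(
                    zm, candidates, seed=int(rng.integers(2**31 - 1)), **kwargs
                )
            else:
                chosen, cv_table = 2, None
            model = sustain.fit_sustain(
                zm, chosen, seed=int(rng.integers(2**31 - 1)), **kwargs
            )
            model.cv_table = cv_table
            assignments = sustain.assign(model, zm).table
            patients = patients.merge(
                assignments[["subject_id", "map_subtype", "expected_stage"]],
                on="subject_id",
                how="left",
            )
            patients["sustain_subtype"] = np.where(
                patients["map_subtype"].notna(),
                "subtype-" + patients["map_subtype"].astype("Int64").astype(str),
                grouping.NON_CPFE,
            )

    estimates, decline_log = _decline_wide(pft, patients, config.lme_partition_col)
    analysis_df = patients.merge(estimates, on="subject_id", how="left")
    if config.trial_subanalysis:
        analysis_df["trial_eligible"] = grouping.trial_eligibility_flags(analysis_df).to_numpy()

    groupings = [primary]
    if "sustain_subtype" in analysis_df.columns:
        groupings.append("sustain_subtype")

    decline_summaries = {}
    for measure in ("fvc", "dlco"):
        cols = {
            "subject_id": analysis_df["subject_id"],
            "absolute_decline": analysis_df.get(f"{measure}_abs_decline"),
        }
        for t in decline.DECLINE_THRESHOLDS[measure]:
            cols[f"decline_ge_{t:g}"] = analysis_df.get(f"{measure}_decline_ge_{t:g}")
        est = pd.DataFrame(cols).dropna(subset=["absolute_decline"])
        for grp in groupings:
            labels = analysis_df.set_index("subject_id")[grp]
            decline_summaries[(measure, grp)] = decline.decline_summary(
                est, labels, measure
            )

    km_results = {}
    for grp in groupings:
        sub = analysis_df.dropna(subset=[grp])
        try:
            km_results[grp] = survival.km_logrank(
                sub["survival_years"], sub["death"], sub[grp].astype(str)
            )
        except ValidationError as e:
            logger.warning("KM skipped for %s: %s", grp, e)

    cox_rows = []
    for grp in groupings:
        for label in analysis_df[grp].dropna().unique():
            sub = analysis_df[analysis_df[grp] == label]
            for measure, cov in DECLINE_COVARIATES:
                if cov not in sub.columns:
                    continue
                data = sub.dropna(subset=[cov])
                try:
                    res = survival.fit_adjusted_cox(
                        data, cov, subgroup=f"{grp}={label}"
                    )
                except ValidationError as e:
                    logger.info("Cox %s/%s ineligible: %s", label, cov, e)
                    res = survival.ineligible_result(
                        f"{grp}={label}", cov, len(data), int(data["death"].sum())
                    )
                except Exception as e:  # non-convergence etc: flagged, not raised
                    logger.warning("Cox %s/%s failed: %s", label, cov, e)
                    res = survival.ineligible_result(
                        f"{grp}={label}", cov, len(data), int(data["death"].sum())
                    )
                cox_rows.append(res.as_row())
    cox_table = pd.DataFrame(cox_rows)

    from . import __version__ as pkg_version

    run_log = {
        "seed": config.seed,
        "version": pkg_version,
        "n_patients": int(len(patients)),
        "n_excluded": int(len(excl)),
        "emphysema_thresholds": list(config.emphysema_thresholds),
        "subtype_mode": config.subtype_mode,
        "n_subtypes": model.n_subtypes if model is not None else None,
        "cohort_config": config.cohort.to_dict() if config.cohort else None,
    }
    bundle = ReportBundle(
        baseline_table=baseline,
        cohort_summaries=summaries,
        decline_estimates=estimates,
        decline_summaries=decline_summaries,
        cox_table=cox_table,
        km_results=km_results,
        subtype_model=model,
        subtype_assignments=assignments,
        patients=analysis_df,
        exclusion_log=pd.concat([excl, decline_log], ignore_index=True),
        run_log=run_log,
    )
    if config.output_dir:
        write_bundle(bundle, config.output_dir)
    return bundle


def write_bundle(bundle: ReportBundle, output_dir) -> None:
    """Write every table of the bundle as CSV/JSON under ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.baseline_table.to_csv(out / "baseline_table.csv", index=False)
    for thr, tab in bundle.cohort_summaries.items():
        tab.to_csv(out / f"cohort_summary_thr{thr:g}.csv", index=False)
    bundle.decline_estimates.to_csv(out / "decline_estimates.csv", index=False)
    for (measure, grp), summ in bundle.decline_summaries.items():
        summ.table.to_csv(out / f"decline_summary_{measure}_{grp}.csv", index=False)
        summ.chi2_tests.to_csv(out / f"decline_tests_{measure}_{grp}.csv", index=False)
    bundle.cox_table.to_csv(out / "cox_models.csv", index=False)
    for grp, km in bundle.km_results.items():
        for label, curve in km.curves.items():
            curve.to_csv(out / f"km_{grp}_{label}.csv", index=False)
    if bundle.subtype_model is not None:
        bundle.subtype_model.save_json(out / "subtype_model.json")
        bundle.subtype_assignments.to_csv(out / "subtype_assignments.csv", index=False)
    bundle.exclusion_log.to_csv(out / "exclusions.csv", index=False)
    with open(out / "run_log.json", "w") as fh:
        json.dump(bundle.run_log, fh, indent=2, default=str)
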