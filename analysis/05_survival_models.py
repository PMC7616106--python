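#!/usr/bin/env python
"""Mortality analysis: KM/log-rank by CPFE class and adjusted Cox models.

For every subgroup (CPFE class at the 10% threshold, and the fitted subtype
labels when available) and every decline covariate (continuous relative
decline and the binary 5/10/15% threshold flags), fits the multivariable
centre-random-intercept Cox model, applying the 8-events-per-covariate rule,
and writes the Table-4-style results.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cpfe_progression import grouping, survival
from cpfe_progression.errors import ValidationError

DECLINE_COVS = [
    ("fvc", "fvc_rel_decline"), ("fvc", "fvc_decline_ge_5"), ("fvc", "fvc_decline_ge_10"),
    ("dlco", "dlco_rel_decline"), ("dlco", "dlco_decline_ge_10"), ("dlco", "dlco_decline_ge_15"),
]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=str, default="results/cohort")
    ap.add_argument("--decline", type=str, default="results/decline")
    ap.add_argument("--out", type=str, default="results/survival")
    args = ap.parse_args()
    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    patients = pd.read_csv(data / "patients.csv")
    patients, _ = grouping.apply_cohort_filter(patients)
    patients["cpfe_class_10"] = grouping.classify_cpfe_series(
        patients["lung_emphysema_pct"], 10.0
    ).astype(str)

    for measure in ("fvc", "dlco"):
        est = pd.read_csv(Path(args.decline) / f"decline_estimates_{measure}.csv")
        ren = {"relative_decline": f"{measure}_rel_decline"}
        ren.update({c: f"{measure}_{c}" for c in est.columns if c.startswith("decline_ge")})
        patients = patients.merge(
            est.rename(columns=ren).drop(columns=["absolute_decline", "measure"]),
            on="subject_id", how="left",
        )

    km = survival.km_logrank(
        patients["survival_years"], patients["death"], patients["cpfe_class_10"]
    )
    print(f"log-rank across CPFE classes: chi2={km.chi2:.1f}, p={km.p_value:.2e}")
    for label, curve in km.curves.items():
        curve.to_csv(out / f"km_{label}.csv", index=False)

    rows = []
    for label, sub in patients.groupby("cpfe_class_10"):
        for measure, cov in DECLINE_COVS:
            df = sub.dropna(subset=[cov])
            try:
                res = survival.fit_adjusted_cox(df, cov, subgroup=label)
            except ValidationError as e:
                print(f"  {label} / {cov}: ineligible ({e})")
                res = survival.ineligible_result(
                    label, cov, len(df), int(df["death"].sum())
                )
            rows.append(res.as_row())
    table = pd.DataFrame(rows)
    table.to_csv(out / "cox_models.csv", index=False)
    fitted = table[table["eligible"]]
    print(f"fitted {len(fitted)} Cox models "
          f"({len(table) - len(fitted)} ineligible by the 8-events-per-covariate rule)")
    show = fitted[["subgroup", "covariate", "c_index", "p_value", "hazard_ratio",
                   "ci_lower", "ci_upper"]]
    print(show.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"wrote {out}/")


if __name__ == "__main__":
    main()
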