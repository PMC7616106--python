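#!/usr/bin/env python
"""Baseline characteristics by CPFE class and interobserver agreement.

Classifies the cohort at the 10% and 15% lung-emphysema thresholds, builds
the baseline comparison table (t-tests / chi-squared), and computes the
agreement statistics from the dual-read subset: per-biomarker
single-determination SDs and Cohen's kappa at 0/5/10/15% emphysema
thresholds.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cpfe_progression import grouping
from cpfe_progression.pipeline import cohort_summary


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=str, default="results/cohort")
    ap.add_argument("--out", type=str, default="results/baseline")
    args = ap.parse_args()
    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    patients = pd.read_csv(data / "patients.csv")
    patients, excl = grouping.apply_cohort_filter(patients)
    print(f"retained {len(patients)} patients ({len(excl)} excluded by 91-day rule)")

    for thr in (10.0, 15.0):
        patients[f"cpfe_class_{thr:g}"] = grouping.classify_cpfe_series(
            patients["lung_emphysema_pct"], thr
        )
        summ = cohort_summary(patients[f"cpfe_class_{thr:g}"])
        summ.to_csv(out / f"cohort_summary_thr{thr:g}.csv", index=False)
        by_class = summ.set_index("class")
        cpfe = by_class.loc["any emphysema (CPFE)"]
        above = by_class.loc[grouping.CPFE_AT_OR_ABOVE]
        print(
            f"threshold {thr:g}%: CPFE {int(cpfe['n'])}/{len(patients)} "
            f"({cpfe['pct']:g}%), of which {int(above['n'])} at/above {thr:g}%"
        )

    baseline = grouping.baseline_comparison(
        patients, "cpfe_class_10",
        continuous=("age", "lung_fibrosis_pct", "lung_emphysema_pct",
                    "fvc_pp_baseline", "dlco_pp_baseline"),
        categorical=("male", "smoking_ever", "antifibrotic_ever"),
    )
    baseline.to_csv(out / "baseline_table.csv", index=False)

    dual = pd.read_csv(data / "dual_reads.csv")
    sdd_rows = []
    for b, g in dual.groupby("biomarker"):
        sdd_rows.append(
            {"biomarker": b,
             "single_determination_sd": grouping.single_determination_sd(g[["read1", "read2"]])}
        )
    pd.DataFrame(sdd_rows).to_csv(out / "interobserver_sd.csv", index=False)

    # emphysema lung % per read, kappa at the clinical thresholds
    emph = dual[dual["biomarker"].str.startswith("emphysema")]
    lung = emph.groupby("subject_id")[["read1", "read2"]].mean()
    kappa_rows = []
    for thr in (0.0, 5.0, 10.0, 15.0):
        lab1 = (lung["read1"] > thr) if thr == 0 else (lung["read1"] >= thr)
        lab2 = (lung["read2"] > thr) if thr == 0 else (lung["read2"] >= thr)
        try:
            k = grouping.cohens_kappa(lab1.to_numpy(), lab2.to_numpy())
        except Exception:
            k = float("nan")
        kappa_rows.append({"threshold_pct": thr, "kappa": k})
        print(f"kappa at {thr:g}% emphysema threshold: {k:.2f}")
    pd.DataFrame(kappa_rows).to_csv(out / "kappa_by_threshold.csv", index=False)
    print(f"wrote {out}/")


if __name__ == "__main__":
    main()
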