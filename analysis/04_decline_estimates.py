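#!/usr/bin/env python
"""Estimate 1-year FVC and DLco decline and summarise it by CPFE class.

Applies the eligibility windows (baseline within 91 days of CT, at least one
follow-up, 18-month horizon), fits the mixed models on both the raw and the
percent-of-baseline scales, and writes per-subject decline estimates plus the
threshold-proportion summary tables with chi-squared and ANOVA/Tukey tests.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cpfe_progression import decline, grouping


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=str, default="results/cohort")
    ap.add_argument("--out", type=str, default="results/decline")
    ap.add_argument("--partition-col", type=str, default=None,
                    help="fit one LME per level of this column (e.g. centre_id)")
    args = ap.parse_args()
    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    patients = pd.read_csv(data / "patients.csv")
    patients, _ = grouping.apply_cohort_filter(patients)
    pft = pd.read_csv(data / "pft_series.csv")
    labels = grouping.classify_cpfe_series(
        patients["lung_emphysema_pct"], 10.0
    )
    labels.index = patients["subject_id"]

    for measure in ("fvc", "dlco"):
        est, excl = decline.estimate_decline(
            pft, patients, measure, args.partition_col
        )
        est.to_csv(out / f"decline_estimates_{measure}.csv", index=False)
        print(f"{measure}: {len(est)} subjects with decline estimates "
              f"({len(excl)} excluded by eligibility windows)")
        print(f"  mean relative decline {est['relative_decline'].mean():.2f}%/yr, "
              f"mean absolute decline {est['absolute_decline'].mean():.1f}")
        summ = decline.decline_summary(est, labels, measure)
        summ.table.to_csv(out / f"decline_summary_{measure}.csv", index=False)
        summ.chi2_tests.to_csv(out / f"decline_chi2_{measure}.csv", index=False)
        if summ.tukey is not None:
            summ.tukey.to_csv(out / f"decline_tukey_{measure}.csv", index=False)
        print(f"  ANOVA on absolute decline: p={summ.anova_p:.3f}")
    print(f"wrote {out}/")


if __name__ == "__main__":
    main()
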