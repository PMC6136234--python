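#!/usr/bin/env python
"""Paired before/after contrast for a pump-therapy switch in a T1D
subgroup (n=10), in two parts.

Part 1 replays the published group means as degenerate one-row tables:
the paired machinery reports the printed reductions (ellipse area
-16.59 mmol^2/l^2, %CV -15.60) with the zero-variance flag set.

Part 2 simulates 10 matched T1D subjects before (MDI-like: %CV 39.9,
mean 7.4) and after (CSII-like: %CV 24.3, mean 7.5, smaller meal
excursions) and runs the two-sided paired t-test per index.
"""

from pathlib import Path

import pandas as pd

from glucodyn.pipeline import subject_metrics
from glucodyn.reference import PUMP_THERAPY_AFTER, PUMP_THERAPY_BEFORE
from glucodyn.simulate import generate_cgm, preset
from glucodyn.stats import paired_before_after

SEED = 7
N_SUBJECTS = 10
METRICS = ["sd1", "sd2", "sfe", "afe", "complexity_index", "alpha1", "alpha2",
           "cv_percent", "tir_hours_per_day"]


def main() -> None:
    Path("results").mkdir(exist_ok=True)

    print("published group-mean deltas (degenerate one-row inputs):")
    for metric in ("afe", "cv_percent", "sd1", "sd2"):
        res = paired_before_after(PUMP_THERAPY_BEFORE, PUMP_THERAPY_AFTER, metric)
        print(f"  {metric:12s} mean difference {res.mean_difference:+.2f} "
              f"(zero-variance flag: {res.zero_variance})")

    before_prof = preset("T1D", cv_percent=39.9, mean_glucose=7.4)
    after_prof = preset("T1D", cv_percent=24.3, mean_glucose=7.5,
                        meal_amp=2.0, meal_width_min=100.0)
    rows_b, rows_a = [], []
    for i in range(N_SUBJECTS):
        sid = f"t1d-{i:02d}"
        sb = generate_cgm(before_prof, seed=SEED + 2 * i, subject_id=sid)
        sa = generate_cgm(after_prof, seed=SEED + 2 * i + 1, subject_id=sid)
        rows_b.append(subject_metrics(sb))
        rows_a.append(subject_metrics(sa))
    before, after = pd.DataFrame(rows_b), pd.DataFrame(rows_a)

    out = []
    for metric in METRICS:
        res = paired_before_after(before, after, metric)
        out.append({"metric": metric, "mean_difference": res.mean_difference,
                    "t": res.t_stat, "p": res.p_value, "n": res.n})
    result = pd.DataFrame(out)
    result.to_csv("results/pump_therapy_contrast.csv", index=False, float_format="%.4f")
    print(f"\nsimulated paired contrast (n={N_SUBJECTS}):")
    print(result.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
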