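"""Published group-level summaries used to calibrate the synthetic cohorts.

The package emulates a clinical CGM study of 177 subjects (22 type 1
diabetic, 143 type 2 diabetic, 12 non-diabetic) monitored at 5-min sampling
over 48 h (576 samples per trace). The raw traces are not public; what is
public are group-level summaries (mean glucose, %CV, time in range,
demographics) and a small number of fully worked per-subject index values.
Those published numbers are collected here, in one place, as:

* calibration targets for the synthetic-cohort presets
  (:data:`GROUP_SUMMARIES`),
* closed-form worked examples for the Poincare descriptors
  (:data:`WORKED_EXAMPLES`), and
* the before/after group means of a pump-therapy (MDI -> CSII) subgroup
  (:data:`PUMP_THERAPY_BEFORE`, :data:`PUMP_THERAPY_AFTER`), used to
  demonstrate the paired comparison on degenerate one-row inputs.

All glucose quantities are mmol/l; AFE is mmol^2/l^2; TIR is h/day.
"""

from __future__ import annotations

import pandas as pd

#: Group-level means (and SDs where used by the covariate generator) for the
#: three study groups. ``duration_median``/``duration_iqr`` are years;
#: therapy codes: 1 = none, 2 = diet with/without oral agents,
#: 3 = oral agents with/without insulin, 4 = insulin alone.
GROUP_SUMMARIES: dict[str, dict] = {
    "ND": {
        "n": 12,
        "mean_glucose": 5.4,
        "mean_glucose_sd": 0.5,
        "cv_percent": 15.7,
        "cv_percent_sd": 3.5,
        "sd_glucose": 0.9,
        "tir_hours_per_day": 23.4,
        "age": (44.3, 12.4),
        "bmi": (27.1, 4.1),
        "carb_intake": (185.6, 35.3),
        "hba1c": (5.0, 0.3),
        "sex_male_fraction": 5 / 12,
        "duration_median": 0.0,
        "duration_iqr": (0.0, 0.0),
        "therapy_probs": {1: 1.0},
    },
    "T2D": {
        "n": 143,
        "mean_glucose": 7.8,
        "mean_glucose_sd": 2.0,
        "cv_percent": 20.2,
        "cv_percent_sd": 7.4,
        "sd_glucose": 1.6,
        "tir_hours_per_day": 17.4,
        "age": (65.4, 8.2),
        "bmi": (30.3, 4.8),
        "carb_intake": (138.8, 50.7),
        "hba1c": (6.8, 1.0),
        "sex_male_fraction": 91 / 143,
        "duration_median": 7.0,
        "duration_iqr": (3.0, 12.0),
        # 42 diet alone + 63 oral only -> code 2/3 split per the coding above
        "therapy_probs": {2: 105 / 143, 3: 18 / 143, 4: 20 / 143},
    },
    "T1D": {
        "n": 22,
        "mean_glucose": 8.0,
        "mean_glucose_sd": 1.7,
        "cv_percent": 36.9,
        "cv_percent_sd": 8.6,
        "sd_glucose": 2.9,
        "tir_hours_per_day": 13.2,
        "age": (43.3, 15.2),
        "bmi": (25.3, 3.9),
        "carb_intake": (211.8, 46.6),
        "hba1c": (7.7, 0.9),
        "sex_male_fraction": 11 / 22,
        "duration_median": 20.5,
        "duration_iqr": (14.8, 29.0),
        "therapy_probs": {4: 1.0},
    },
}

#: Fully worked single-subject index values (one subject per group) from the
#: published study: mean glucose and %CV together with the Poincare
#: descriptors (lag 60 min), the multiscale-entropy complexity index, and the
#: DFA exponents. The T1D row's SD1/SD2/AFE triple is arithmetically closed
#: (AFE = pi * SD1 * SD2) and serves as the worked acceptance example.
WORKED_EXAMPLES = pd.DataFrame(
    [
        ("777773", "ND", 5.6, 23.42, 0.81, 2.00, 5.08, 5.47, 1.81, 1.32),
        ("128701", "T2D", 6.1, 26.27, 1.11, 2.39, 8.31, 4.66, 1.83, 1.24),
        ("125264", "T1D", 8.7, 32.37, 1.48, 3.67, 17.06, 2.86, 2.02, 1.53),
    ],
    columns=[
        "subject_id",
        "group",
        "mean_glucose",
        "cv_percent",
        "sd1",
        "sd2",
        "afe",
        "complexity_index",
        "alpha1",
        "alpha2",
    ],
)

#: Group means for 10 type 1 diabetic patients before switching from multiple
#: daily injections (MDI) to pump therapy (CSII), and 6 months after.
PUMP_THERAPY_BEFORE = pd.DataFrame(
    [
        {
            "subject_id": "t1d-subgroup-mean",
            "sd1": 1.66,
            "sd2": 4.37,
            "sfe": 2.75,
            "afe": 23.07,
            "complexity_index": 3.09,
            "alpha1": 2.04,
            "alpha2": 1.43,
            "hba1c": 8.2,
            "mean_glucose": 7.4,
            "cv_percent": 39.9,
            "sd_glucose": 2.9,
            "tir_hours_per_day": 13.0,
        }
    ]
)

PUMP_THERAPY_AFTER = pd.DataFrame(
    [
        {
            "subject_id": "t1d-subgroup-mean",
            "sd1": 0.81,
            "sd2": 2.47,
            "sfe": 3.07,
            "afe": 6.48,
            "complexity_index": 1.93,
            "alpha1": 2.09,
            "alpha2": 1.57,
            "hba1c": 7.7,
            "mean_glucose": 7.5,
            "cv_percent": 24.3,
            "sd_glucose": 1.8,
            "tir_hours_per_day": 17.7,
        }
    ]
)
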