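# glucodyn

Variability analysis of continuous glucose monitoring (CGM) time series
across three complementary domains, with a synthetic-cohort generator and
the cohort-level statistics needed to compare diabetic and non-diabetic
glucose dynamics.

Conventional glycemic-variability metrics (SD, %CV) measure only the
*amplitude* of glucose excursions. The dynamical structure of a glucose
trace — how regular, how persistent, how correlated in time — carries
independent clinical information. `glucodyn` implements, for 5-min CGM
traces (nominally 576 samples per 48-h window):

* **Geometric domain — lagged Poincaré plots.** Pairs (G(t), G(t+Δt)) at a
  delay Δt (default 60 min) are summarized by the dispersions across and
  along the identity line, SD1 and SD2 (rotated-coordinate SDs of
  (x−y)/√2 and (x+y)/√2), and the shape and area of the fitting ellipse,
  SFE = SD2/SD1 and AFE = π·SD1·SD2.
* **Information domain — multiscale entropy (MSE).** Sample entropy
  SampEn(m=2, r=0.15·SD) = −ln(A/B) on coarse-grained copies of the series
  at scales τ = 1..5 (non-overlapping window means, 576 → 115 samples at
  τ = 5), with r fixed from the original series; the complexity index is
  the sum of the per-scale entropies.
* **Fractal-scaling domain — detrended fluctuation analysis (DFA).** The
  RMS residual F(n) of the integrated, box-wise linearly detrended series
  scales as n^α; the slope of log F vs log n is fitted over a short range
  (α1, boxes of 4–16 samples) and a long range (α2, 16–144 samples) around
  the crossover at n = 16.
* **Linear metrics** — mean glucose, sample SD, %CV = 100·SD/mean, and
  time in the 3.9–8.9 mmol/l target range in h/day.
* **Cohort statistics** — ANOVA + pairwise t-tests with Holm adjustment,
  Spearman correlation matrices across domains, standardized (β) multiple
  regression of time-in-range on a covariate core model (age, sex, diabetes
  duration, BMI, carbohydrate intake, antidiabetic therapy) plus %CV and a
  dynamical index, with VIF and Durbin–Watson diagnostics, and paired
  before/after comparisons for therapy changes.

Because raw clinical CGM traces with this design are not public, the
package ships a seeded synthetic generator (`glucodyn.simulate`):
circadian + meal + fractional-Gaussian-noise + sensor-noise traces whose
mean, %CV, and Hurst exponent are controllable, with group presets
targeting the published cohort summaries (ND 5.4 mmol/l / 15.7%,
T2D 7.8 / 20.2, T1D 8.0 / 36.9). Exact Davies–Harte fGn synthesis doubles
as the calibration oracle for the DFA estimator (slope ≈ H).

## Worked example

```python
from glucodyn import (generate_cgm, compute_gv, poincare_descriptors,
                      mse_index, dfa_exponents)
from glucodyn.simulate import preset

series = generate_cgm(preset("T1D"), n_points=576, seed=7)
gv = compute_gv(series)
pc = poincare_descriptors(series, lag_min=60)
mse = mse_index(series)
dfa = dfa_exponents(series)
print(f"mean {gv.mean_glucose:.1f} mmol/l, CV {gv.cv_percent:.1f}%, "
      f"TIR {gv.tir_hours_per_day:.1f} h/day")
print(f"SD1 {pc.sd1:.2f}, SD2 {pc.sd2:.2f}, SFE {pc.sfe:.2f}, AFE {pc.afe:.2f}")
print(f"complexity index {mse.complexity_index:.2f}, "
      f"alpha1 {dfa.alpha1:.2f}, alpha2 {dfa.alpha2:.2f}")
```

prints

```
mean 8.0 mmol/l, CV 36.9%, TIR 15.2 h/day
SD1 1.78, SD2 3.75, SFE 2.11, AFE 20.97
complexity index 4.87, alpha1 1.52, alpha2 1.37
```

i.e. a type-1-diabetes-like trace: large ellipse area (wide, elongated
Poincaré cloud → high amplitude with strong 60-min correlation), low
complexity index (smooth, meal-dominated signal), and elevated scaling
exponents, with under 15 h/day in the 3.9–8.9 mmol/l target range.

The full simulated study lives in `analysis/` as numbered drivers:

```bash
python analysis/01_simulate_cohort.py          # 12 ND + 143 T2D + 22 T1D subjects
python analysis/02_per_subject_indices.py      # 13 indices per subject
python analysis/03_group_comparisons.py        # ANOVA + Holm pairwise tests
python analysis/04_correlations_and_regressions.py
python analysis/05_pump_therapy_contrast.py    # paired MDI -> CSII contrast
```

Each script prints what it found and writes its tables under `results/`.
On the synthetic cohort the published directions are recovered: Poincaré
descriptors and DFA exponents increase ND → T2D → T1D while the complexity
index decreases; the dynamical indices correlate positively (MSE
negatively) with %CV; and SD1/SD2/AFE are the dominant negative predictors
of time-in-range in the fully adjusted models.

There is also a CLI (`glucodyn simulate|qc|metrics|poincare|mse|dfa|stats|run`)
wrapping the same library calls; `glucodyn run -c config.yaml` executes the
whole pipeline from a YAML spec and writes a manifest recording every
toggle in effect.

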