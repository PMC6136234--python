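# Methods

`glucodyn` analyses continuous glucose monitoring (CGM) time series — 5-min
interstitial glucose samples, nominally 576 points per 48-h window — across
three variability domains alongside conventional glycemic-variability
metrics, and provides a synthetic-cohort generator so the full pipeline is
testable and calibratable without patient data. This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Linear metrics (`glucodyn.gv`)

Mean glucose, SD, %CV = 100·SD/mean, and time in range (TIR). Conventions:

* **Sample (n−1) SD everywhere** in the package (gv, Poincaré, entropy
  tolerance). The population-variance alternative is exposed where it
  matters (`poincare_descriptors(ddof=0)`).
* **TIR** counts samples in the closed interval [3.9, 8.9] mmol/l (both
  bounds inclusive, configurable) and scales the fraction to hours per day.
* Metrics are computed once over the supplied window. A
  `per_day_average` option computes mean/SD/%CV per 24-h block and
  averages, since published summaries are sometimes per-day averages; the
  default is the single-window computation.

## Poincaré descriptors (`glucodyn.poincare`)

All overlapping lagged pairs (G(t), G(t+Δt)) are formed at a delay Δt that
must be a multiple of the sampling interval (default 60 min ⇒ lag 12
samples at 5-min sampling; 30 and 120 min are supported probe values). SD1
and SD2 are the sample SDs of the rotated coordinates (x−y)/√2 and
(x+y)/√2 — equivalent to the fitting-ellipse minor/major axis dispersions —
and SFE = SD2/SD1, AFE = π·SD1·SD2. Choices: rotated-coordinate variances
rather than geometric ellipse fitting (exact, reproducible, identical to
the standard descriptor definitions); overlapping pairs at stride 1;
SFE is flagged undefined (NaN) for constant series rather than raising.
The identity SD1² + SD2² = Var(x) + Var(y) holds exactly and is asserted in
the tests.

## Multiscale entropy (`glucodyn.complexity`)

Coarse-graining at scale τ takes non-overlapping window means, output
length ⌊N/τ⌋ (576 → 115 at τ = 5). SampEn(m, r) = −ln(A/B) with Chebyshev
distance, natural log, ordered pairs i ≠ j, self-matches excluded, and
template starts 0..N−m−1 for both lengths m and m+1 — the convention of the
standard multiscale-entropy C implementation, which makes the counts (A, B)
integer-comparable against a brute-force double loop (asserted in tests).
Defaults m = 2, r = 0.15·SD, scales 1–5; **r is computed once from the
scale-1 series and held fixed across scales**, so that coarse-graining's
variance shrinkage registers as reduced entropy rather than being
renormalised away. The complexity index is the sum of per-scale entropies;
a scale with zero matches is reported NaN and marks the index `partial`
(never silently replaced). The SD entering r is taken after any gap
filling, recorded in the result.

## Detrended fluctuation analysis (`glucodyn.dfa`)

The mean-centred series is integrated; the profile is cut into
non-overlapping boxes anchored at the series start (trailing remainder
discarded — the fluctuation sum runs over the boxes once, no reversed
second pass; both-ends analysis was considered and rejected to keep the
estimator identical to its defining equation); a first-order polynomial is
removed per box; F(n) is the RMS residual over the covered points. Box
sizes are evaluated on a log-spaced integer grid (~12 per decade,
deduplicated, recorded in the result) capped at ⌊N/2⌋, and the slope of
log₁₀F vs log₁₀n is fitted by OLS over the short range (α1) and long range
(α2), with the crossover size n = 16 included in both fits.

Numerical choices:

* **min_box = 4 by default.** With linear detrending, 2-point boxes fit
  exactly (F contribution 0, log F undefined) and 3-point boxes are
  near-degenerate; the short-range fit therefore defaults to n ∈ [4, 16].
  The literal range [2, 16] is available via `min_box=2`, with
  zero-fluctuation box sizes excluded from the log-log fit. The
  conventional time label "1.25 h" for the crossover and the 16-sample
  count disagree by 5 min at 5-min sampling; the package follows the
  sample counts.
* `scaling_exponent` is the single-exponent calibration estimator: it fits
  n ∈ [16, min(512, N/4)] because first-order DFA is biased at the
  smallest boxes and unstable at the largest; at N = 4096 this recovers
  the Hurst exponent of fractional Gaussian noise to within ±0.1 over
  H ∈ {0.3, 0.5, 0.7, 0.9}, and 1.5 for integrated white noise (asserted).

## Synthetic CGM generator (`glucodyn.simulate`)

One trace is mean + fluctuation, where the fluctuation sums a 24-h
circadian cosine (acrophase 16:00), Gaussian meal bumps (default clock
times 07:00/12:00/18:00, centres jittered ±15 min SD, amplitudes jittered
±30%), fractional Gaussian noise, and white sensor noise. The centred
fluctuation is rescaled in **one affine pass** to the target
SD = %CV/100·mean (no iterative search — deterministic and auditable),
shifted to the target mean, and floor-clipped at 2.2 mmol/l with the
clipping fraction recorded (a warning flag above 5%; clipping rather than
rejection sampling keeps the seed→output map simple). fGn synthesis is the
exact Davies–Harte circulant embedding; negative circulant eigenvalues (not
observed for fGn) would be clipped with an `exact=False` flag recorded in
the series metadata.

Group presets target the published group-level mean glucose and %CV
(ND 5.4 / 15.7, T2D 7.8 / 20.2, T1D 8.0 / 36.9 mmol/l / %). The structural
parameters are fixed physiological choices: absolute sensor noise roughly
constant across groups (0.30/0.25/0.20 mmol/l), meal amplitude and width
growing with diabetes severity (1.0/60 min → 2.0/90 → 3.5/120), circadian
amplitude 0.3/0.8/1.0 mmol/l, and Hurst exponent 0.60/0.75/0.90. Because
the whole fluctuation is jointly rescaled, these parameters control the
*composition* of the variance: the fraction contributed by irregular sensor
noise falls from ~23% (ND) to ~2% (T1D), which is what drives the entropy
ordering ND > T2D > T1D, while the absolute SD (via %CV·mean) drives
SD1/SD2/AFE ordering T1D > T2D > ND.

Cohorts spawn one child generator per subject from a single `SeedSequence`
(bitwise-reproducible). Covariates (age, sex, BMI, carbohydrate intake,
HbA1c, therapy code 1–4, diabetes duration as a log-normal matched to the
published median/IQR) are drawn around the published group values. By
default every subject hits the preset mean/%CV exactly — the calibration
condition under which the ordering-recovery checks run. `target_jitter=True`
additionally draws per-subject mean/%CV targets with the published
between-subject SDs (e.g. %CV 36.9 ± 8.6 in T1D); the analysis scripts use
this mode because the covariate-adjusted regressions are degenerate when
%CV has no within-group variance.

What the generator does **not** emulate: physiological insulin–glucose
feedback dynamics, sensor drift/calibration artifacts, day-to-day
non-stationarity of meal content, hypoglycemic counter-regulation, or any
TIR-consistent constraint beyond mean/%CV (matching the published per-group
TIR simultaneously is not attempted). Passing tests therefore show that the
estimators recover known structure and orderings under a controlled additive
model — not that real CGM traces satisfy that model. In particular the
published DFA exponents for patients lie near 1.8–2.0 (a strongly
non-stationary, fBm-like regime), whereas pure fGn inputs have slopes < 1;
the full synthetic traces reach α1 ≈ 0.8–1.4 only through their
deterministic meal/circadian trends, so only the *ordering* of the
exponents across groups is claimed, never their level.

## Cohort statistics (`glucodyn.stats`)

Delegated to scipy/statsmodels with the conventions fixed here: one-way
ANOVA plus all pairwise Welch-less two-sample t-tests with Holm step-down
adjustment over the pairwise family; Spearman correlations with mid-ranked
ties; OLS on the z-scored response and z-scored continuous terms, with sex
coded 0/1 (M = 1) and therapy as a single ordinal numeric 1–4 (fidelity to
the published coding, not dummy-expanded); VIF per term and Durbin–Watson
on residuals in table row order (row order is a recorded, seedable cohort
property). Perfect collinearity raises an error naming the offending terms.
Negative adjusted R² is reported as 0 with an explicit flag. The TIR models
fit TIR ~ core covariates (age, sex, diabetes duration, BMI, carbohydrate
intake, therapy) + %CV + one dynamical index; `subjects="patients"` drops
the non-diabetic group (relevant whenever diabetes duration is a term —
ND durations are 0 by construction), and stepwise forward selection of the
core covariates (p-to-enter 0.05, a conventional default) is optional while
%CV and the index are always kept. The paired before/after comparison is a
two-sided paired t-test; zero-variance differences (including degenerate
one-row group-mean inputs) are flagged, with the mean difference always
reported.

## Problem sizes

The defaults used by the tests and analysis scripts are the package's own
choices: 576-point series; ordering recovery over 50 cohorts of 8
subjects/group; DFA calibration over 100 replicates of length 4096 per
Hurst value; SampEn oracle comparison over 100 series of length ≤ 300;
Holm family-wise error over 1000 simulated 3-group tables of 10
subjects/group; the full simulated study uses 177 subjects (12/143/22).

## Known limitations

* The additive generator cannot reproduce level-dependent variability
  (glucose variance growing with glucose level within a trace).
* SampEn at scale 1 of the synthetic traces is higher than published CGM
  values because white sensor noise enters additively; the complexity
  index is therefore compared across groups, not against published levels.
* `fill_gaps` assumes grid-aligned timestamps; irregular sampling is out
  of scope.
* The Davies–Harte fallback path (negative circulant eigenvalues) is
  defensive only; it is not exercised by fGn autocovariances.
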