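"""Synthetic CGM cohorts with controllable statistical structure.

The generative model for one 48-h trace is additive:

    glucose(t) = mean + [ circadian sinusoid + meal pulses
                          + fractional Gaussian noise + white sensor noise ]

where the bracketed fluctuation is centred and affinely rescaled in a single
pass so that the realized series mean and coefficient of variation hit the
profile targets, then floor-clipped at 2.2 mmol/l (below the clinically
relevant hypoglycemic region) with the clipping fraction recorded.

Fractional Gaussian noise (fGn) supplies the tunable fractal backbone: a
zero-mean stationary Gaussian sequence whose detrended-fluctuation slope
equals its Hurst exponent H, which makes it the natural calibration oracle
for the DFA estimator. Synthesis is exact (Davies-Harte circulant
embedding); every random draw is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from glucodyn.cohort import SubjectRecord
from glucodyn.errors import ParameterError
from glucodyn.reference import GROUP_SUMMARIES
from glucodyn.series import GlucoseSeries

#: Glucose floor applied to every synthetic trace, mmol/l.
CLIP_FLOOR = 2.2

#: Default meal clock times (hours after midnight); the generator starts
#: every simulated recording at midnight.
DEFAULT_MEAL_HOURS = (7.0, 12.0, 18.0)

#: Circadian acrophase (hours after midnight) of the background sinusoid.
CIRCADIAN_PEAK_HOUR = 16.0

MINUTES_PER_DAY = 1440.0


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

def fgn_autocovariance(hurst: float, lags: np.ndarray) -> np.ndarray:
    """Autocovariance of unit-variance fGn at integer lags.

    gamma(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})
    """
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1.0) ** h2 - 2.0 * k**h2 + np.abs(k - 1.0) ** h2)


def _davies_harte(hurst: float, n: int, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Exact circulant-embedding synthesis of length-n unit-variance fGn.

    Returns ``(sequence, exact)``; ``exact`` is False when the circulant
    spectrum had negative eigenvalues that were clipped to zero (a spectral
    approximation — does not occur for fGn in practice, but the flag is
    recorded rather than silently ignored).
    """
    gamma = fgn_autocovariance(hurst, np.arange(n + 1))
    # first row of the 2n-circulant: gamma(0..n), gamma(n-1..1)
    row = np.concatenate([gamma, gamma[n - 1 : 0 : -1]])
    lam = np.fft.fft(row).real
    exact = True
    if lam.min() < -1e-10 * max(lam.max(), 1.0):
        exact = False
    lam = np.clip(lam, 0.0, None)

    m = 2 * n
    gn = rng.standard_normal(m)
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * gn[0]
    w[n] = np.sqrt(lam[n] / m) * gn[n]
    k = np.arange(1, n)
    scale = np.sqrt(lam[k] / (2.0 * m))
    w[k] = scale * (gn[k] + 1j * gn[m - k])
    w[m - k] = np.conj(w[k])
    x = np.fft.fft(w).real[:n]
    return x, exact


def generate_fgn(
    hurst: float,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zero-mean, unit-variance fractional Gaussian noise of length ``n``.

    Deterministic given ``seed`` (or an externally managed ``rng``).
    """
    if not 0.0 < hurst < 1.0:
        raise ParameterError(f"hurst must lie in (0, 1), got {hurst}")
    if n < 8:
        raise ParameterError(f"need n >= 8 for circulant embedding, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    x, _ = _davies_harte(hurst, n, rng)
    return x


# ---------------------------------------------------------------------------
# profiles and presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimProfile:
    """Targets and structural parameters for one simulated subject group.

    ``mean_glucose`` and ``cv_percent`` are hit exactly (pre-clipping) by an
    affine rescale; the remaining parameters only set the *composition* of
    the fluctuation — how much of the variance is smooth (circadian, meals,
    fGn) versus irregular (sensor noise) — which is what the entropy and
    scaling analyses see.
    """

    label: str
    mean_glucose: float  # mmol/l
    cv_percent: float  # target %CV
    hurst: float  # fGn Hurst exponent, in (0, 1)
    circadian_amp: float = 0.5  # mmol/l, sinusoid amplitude
    meal_count_per_day: int = 3
    meal_amp: float = 1.5  # mmol/l, nominal bump height
    meal_width_min: float = 90.0  # full width at half maximum, minutes
    noise_sd: float = 0.25  # mmol/l white measurement noise
    fgn_sd: float = 0.4  # mmol/l raw weight of the fGn component

    def __post_init__(self) -> None:
        if self.mean_glucose <= 0:
            raise ParameterError("mean_glucose must be positive")
        if not 0.0 < self.hurst < 1.0:
            raise ParameterError("hurst must lie in (0, 1)")
        if self.cv_percent < 0:
            raise ParameterError("cv_percent must be >= 0")
        for name in ("circadian_amp", "meal_amp", "meal_width_min", "noise_sd", "fgn_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.meal_count_per_day < 0:
            raise ParameterError("meal_count_per_day must be >= 0")


#: Group presets. Mean glucose and %CV are the published group means; the
#: structural parameters encode impaired glucoregulation with diabetes
#: severity: larger and broader postprandial excursions, a stronger
#: circadian component, a higher Hurst exponent (smoother, more persistent
#: fluctuation), and a sensor-determined noise floor that is roughly
#: constant in absolute terms across groups.
PRESETS: dict[str, SimProfile] = {
    "ND": SimProfile(
        label="ND",
        mean_glucose=GROUP_SUMMARIES["ND"]["mean_glucose"],
        cv_percent=GROUP_SUMMARIES["ND"]["cv_percent"],
        hurst=0.60,
        circadian_amp=0.3,
        meal_count_per_day=3,
        meal_amp=1.0,
        meal_width_min=60.0,
        noise_sd=0.30,
    ),
    "T2D": SimProfile(
        label="T2D",
        mean_glucose=GROUP_SUMMARIES["T2D"]["mean_glucose"],
        cv_percent=GROUP_SUMMARIES["T2D"]["cv_percent"],
        hurst=0.75,
        circadian_amp=0.8,
        meal_count_per_day=3,
        meal_amp=2.0,
        meal_width_min=90.0,
        noise_sd=0.25,
    ),
    "T1D": SimProfile(
        label="T1D",
        mean_glucose=GROUP_SUMMARIES["T1D"]["mean_glucose"],
        cv_percent=GROUP_SUMMARIES["T1D"]["cv_percent"],
        hurst=0.90,
        circadian_amp=1.0,
        meal_count_per_day=3,
        meal_amp=3.5,
        meal_width_min=120.0,
        noise_sd=0.20,
    ),
}


def preset(label: str, **overrides) -> SimProfile:
    """A copy of a named preset, optionally with fields overridden."""
    try:
        prof = PRESETS[label]
    except KeyError:
        raise ParameterError(f"unknown preset {label!r}; known: {sorted(PRESETS)}") from None
    return replace(prof, **overrides) if overrides else prof


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a multi-group synthetic cohort.

    With ``target_jitter`` each subject's mean-glucose and %CV targets are
    drawn around the group values using the published between-subject SDs
    (e.g. %CV 36.9 +/- 8.6 for T1D), instead of every subject hitting the
    group mean exactly. Off by default: the exact-preset cohort is the
    calibration condition; the jittered cohort is the realistic one used
    for covariate-adjusted statistics.
    """

    groups: tuple[tuple[SimProfile, int], ...]
    n_points: int = 576
    interval_min: float = 5.0
    seed: int = 0
    target_jitter: bool = False

    def __post_init__(self) -> None:
        if not self.groups:
            raise ParameterError("cohort spec needs at least one group")
        for prof, n_sub in self.groups:
            if n_sub < 1:
                raise ParameterError(f"group {prof.label!r} needs >= 1 subject")
        if self.n_points < 32:
            raise ParameterError("n_points must be >= 32")
        if self.interval_min <= 0:
            raise ParameterError("interval_min must be positive")


# ---------------------------------------------------------------------------
# trace generation
# ---------------------------------------------------------------------------

def _meal_hours(count: int) -> np.ndarray:
    if count <= len(DEFAULT_MEAL_HOURS):
        return np.asarray(DEFAULT_MEAL_HOURS[:count], dtype=float)
    # more than three meals: spread evenly across waking hours 07:00-22:00
    return np.linspace(7.0, 22.0, count)


def _meal_component(
    t_min: np.ndarray, profile: SimProfile, rng: np.random.Generator
) -> np.ndarray:
    out = np.zeros_like(t_min)
    if profile.meal_count_per_day == 0 or profile.meal_amp == 0:
        return out
    n_days = int(np.ceil((t_min[-1] + 1.0) / MINUTES_PER_DAY))
    sigma = profile.meal_width_min / 2.355  # FWHM -> Gaussian sigma
    hours = _meal_hours(profile.meal_count_per_day)
    for day in range(n_days):
        for h in hours:
            center = day * MINUTES_PER_DAY + h * 60.0 + rng.normal(0.0, 15.0)
            amp = profile.meal_amp * rng.uniform(0.7, 1.3)
            out += amp * np.exp(-0.5 * ((t_min - center) / sigma) ** 2)
    return out


def generate_cgm(
    profile: SimProfile,
    n_points: int = 576,
    interval_min: float = 5.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim-000",
) -> GlucoseSeries:
    """One synthetic CGM trace matching the profile's mean and %CV.

    The centred fluctuation (circadian + meals + fGn + noise) is rescaled in
    one affine pass to the target SD = ``cv_percent/100 * mean_glucose``,
    shifted to the target mean, and floor-clipped at 2.2 mmol/l. The clipping
    fraction, realized mean/%CV, and the fGn exactness flag are recorded in
    ``series.meta``; a clipping fraction above 5% sets a warning flag rather
    than failing.
    """
    if n_points < 32:
        raise ParameterError("n_points must be >= 32")
    if interval_min <= 0:
        raise ParameterError("interval_min must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    t_min = np.arange(n_points, dtype=float) * interval_min
    phase = 2.0 * np.pi * (t_min - CIRCADIAN_PEAK_HOUR * 60.0) / MINUTES_PER_DAY
    circadian = profile.circadian_amp * np.cos(phase)
    meals = _meal_component(t_min, profile, rng)
    if profile.fgn_sd > 0:
        fgn_raw, fgn_exact = _davies_harte(profile.hurst, n_points, rng)
        fgn = profile.fgn_sd * fgn_raw
    else:
        fgn = np.zeros(n_points)
        fgn_exact = True
    noise = profile.noise_sd * rng.standard_normal(n_points)

    fluct = circadian + meals + fgn + noise
    fluct = fluct - fluct.mean()
    target_sd = profile.cv_percent / 100.0 * profile.mean_glucose
    raw_sd = float(np.std(fluct, ddof=1))
    meta: dict = {"fgn_exact": fgn_exact, "profile_label": profile.label}
    if target_sd == 0.0 or raw_sd == 0.0:
        fluct = np.zeros(n_points)
        if target_sd > 0.0:
            meta["warning"] = "no fluctuation components; %CV target unreachable"
    else:
        fluct *= target_sd / raw_sd

    values = profile.mean_glucose + fluct
    clip_frac = float(np.mean(values < CLIP_FLOOR))
    values = np.maximum(values, CLIP_FLOOR)
    meta["clip_fraction"] = clip_frac
    if clip_frac > 0.05:
        meta["warning"] = (
            f"%CV target required clipping {100 * clip_frac:.1f}% of samples"
        )
    meta["realized_mean"] = float(values.mean())
    mean = values.mean()
    meta["realized_cv_percent"] = float(100.0 * values.std(ddof=1) / mean)

    return GlucoseSeries(
        subject_id=subject_id,
        values=values,
        interval_min=interval_min,
        t0="2000-01-01T00:00:00",
        group=profile.label,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

_GENERIC_COVARIATES = {
    "age": (50.0, 10.0),
    "bmi": (27.0, 4.0),
    "carb_intake": (180.0, 40.0),
    "hba1c": (6.5, 1.0),
    "sex_male_fraction": 0.5,
    "duration_median": 5.0,
    "duration_iqr": (2.0, 10.0),
    "therapy_probs": {1: 1.0},
}


def _draw_duration(summ: dict, rng: np.random.Generator) -> float:
    median = summ["duration_median"]
    if median <= 0:
        return 0.0
    q1, q3 = summ["duration_iqr"]
    # log-normal matched to the published median and interquartile range
    sigma = (np.log(q3) - np.log(q1)) / (2.0 * 0.6745)
    return float(np.exp(rng.normal(np.log(median), sigma)))


def _draw_record(
    subject_id: str, label: str, rng: np.random.Generator
) -> SubjectRecord:
    summ = {**_GENERIC_COVARIATES, **GROUP_SUMMARIES.get(label, {})}
    age = max(18.0, rng.normal(*summ["age"]))
    bmi = max(16.0, rng.normal(*summ["bmi"]))
    carb = max(50.0, rng.normal(*summ["carb_intake"]))
    hba1c = max(4.0, rng.normal(*summ["hba1c"]))
    sex = "M" if rng.random() < summ["sex_male_fraction"] else "F"
    duration = _draw_duration(summ, rng)
    codes = np.array(list(summ["therapy_probs"].keys()))
    probs = np.array(list(summ["therapy_probs"].values()), dtype=float)
    therapy = int(rng.choice(codes, p=probs / probs.sum()))
    return SubjectRecord(
        subject_id=subject_id,
        group=label,
        age=age,
        sex=sex,
        diabetes_duration=duration,
        bmi=bmi,
        carb_intake=carb,
        therapy_code=therapy,
        hba1c=hba1c,
    )


def _jittered_profile(profile: SimProfile, rng: np.random.Generator) -> SimProfile:
    summ = GROUP_SUMMARIES.get(profile.label)
    if summ is None:
        return profile
    mean = max(3.0, rng.normal(summ["mean_glucose"], summ["mean_glucose_sd"]))
    cv = max(5.0, rng.normal(summ["cv_percent"], summ["cv_percent_sd"]))
    return replace(profile, mean_glucose=mean, cv_percent=cv)


def generate_cohort(spec: CohortSpec) -> tuple[list[GlucoseSeries], list[SubjectRecord]]:
    """One series + covariate record per subject, reproducible from the seed.

    Per-subject generators are spawned from a single ``SeedSequence`` so the
    output is bitwise-stable under the same spec and independent of the
    order in which subjects would be consumed.
    """
    ss = np.random.SeedSequence(spec.seed)
    total = sum(n for _, n in spec.groups)
    children = ss.spawn(total)
    series_list: list[GlucoseSeries] = []
    records: list[SubjectRecord] = []
    idx = 0
    for gi, (profile, n_sub) in enumerate(spec.groups):
        for si in range(n_sub):
            rng = np.random.default_rng(children[idx])
            sid = f"{profile.label.lower()}{gi}-{si:03d}"
            rec = _draw_record(sid, profile.label, rng)
            subject_profile = (
                _jittered_profile(profile, rng) if spec.target_jitter else profile
            )
            series = generate_cgm(
                subject_profile,
                n_points=spec.n_points,
                interval_min=spec.interval_min,
                rng=rng,
                subject_id=sid,
            )
            series_list.append(series)
            records.append(rec)
            idx += 1
    return series_list, records


def cohort_spec_from_dict(cfg: dict) -> CohortSpec:
    """Build a :class:`CohortSpec` from a plain config mapping (YAML/JSON).

    Expected shape::

        groups:
          - {preset: T1D, n_subjects: 22}            # or label+explicit fields
          - {label: custom, n_subjects: 5, mean_glucose: 7.0, cv_percent: 25,
             hurst: 0.8}
        n_points: 576
        interval_min: 5
        seed: 42
    """
    try:
        raw_groups: Sequence[dict] = cfg["groups"]
    except (KeyError, TypeError):
        raise ParameterError("cohort config must contain a 'groups' list") from None
    groups = []
    for g in raw_groups:
        g = dict(g)
        n_sub = int(g.pop("n_subjects"))
        if "preset" in g:
            prof = preset(g.pop("preset"), **g)
        else:
            prof = SimProfile(**g)
        groups.append((prof, n_sub))
    return CohortSpec(
        groups=tuple(groups),
        n_points=int(cfg.get("n_points", 576)),
        interval_min=float(cfg.get("interval_min", 5.0)),
        seed=int(cfg.get("seed", 0)),
        target_jitter=bool(cfg.get("target_jitter", False)),
    )
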