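"""Detrended fluctuation analysis (DFA) with a two-range crossover fit.

The series B(i) is mean-centred and integrated,

    y(k) = sum_{i<=k} (B(i) - B_ave),

the profile y is cut into floor(N/n) non-overlapping boxes of n points, a
least-squares line is removed per box, and the root-mean-square residual
F(n) over the covered points is recorded. For a self-affine signal
F(n) ~ n^alpha; the slope of log10 F vs log10 n is the scaling exponent.
Glucose profiles show a crossover, so the slope is fitted separately over a
short range (alpha1, default boxes of 4-16 samples, i.e. up to ~80 min at
5-min sampling) and a long range (alpha2, 16-144 samples), with the
crossover box size 16 included in both fits.

Note on the smallest boxes: with first-order detrending a 2-point box is
fitted exactly (zero residual, log F undefined), so the default minimum box
size is 4; ``min_box=2`` remains available, with zero-residual box sizes
excluded from the log-log fit.

For fractional Gaussian noise the exponent equals the Hurst parameter H,
which this package exploits as a calibration oracle
(:func:`scaling_exponent`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from glucodyn.errors import ParameterError
from glucodyn.series import GlucoseSeries

DEFAULT_SHORT_RANGE = (4, 16)
DEFAULT_LONG_RANGE = (16, 144)
DEFAULT_MIN_BOX = 4
#: Approximate number of box sizes evaluated per decade of n.
GRID_DENSITY = 12


@dataclass(frozen=True)
class DFAResult:
    box_sizes: np.ndarray
    fluctuations: np.ndarray  # F(n), mmol/l
    alpha1: float  # nan when undefined
    alpha2: float
    fit_range_short: tuple[int, int]
    fit_range_long: tuple[int, int]
    fit_r2_short: float
    fit_r2_long: float


def integrate_series(values: np.ndarray) -> np.ndarray:
    """Cumulative sum of the mean-centred series; the last element is 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("need at least 2 samples")
    return np.cumsum(v - v.mean())


def fluctuation(y: np.ndarray, n: int, min_box: int = 2) -> float:
    """RMS residual F(n) of box-wise linear detrending of the profile y.

    Boxes are anchored at the start; the trailing remainder (fewer than n
    points) is discarded, and F is normalised by the N' = n*floor(N/n)
    covered points.
    """
    y = np.asarray(y, dtype=float)
    if n < min_box:
        raise ParameterError(f"box size {n} below minimum {min_box}")
    n_boxes = y.size // n
    if n_boxes < 1:
        raise ParameterError(f"box size {n} exceeds half the profile length")
    covered = n_boxes * n
    boxes = y[:covered].reshape(n_boxes, n)
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    denom = float((tc**2).sum())
    if denom == 0.0:  # n == 1: residuals are identically zero
        return 0.0
    slope = boxes @ tc / denom
    resid = boxes - boxes.mean(axis=1, keepdims=True) - slope[:, None] * tc[None, :]
    return float(np.sqrt((resid**2).sum() / covered))


def _log_grid(n_min: int, n_max: int) -> np.ndarray:
    """Deduplicated integer box sizes, ~GRID_DENSITY per decade, inclusive."""
    if n_min > n_max:
        return np.array([], dtype=int)
    n_steps = max(2, int(math.ceil(GRID_DENSITY * math.log10(max(n_max / n_min, 1.0001)))))
    grid = np.unique(np.round(np.geomspace(n_min, n_max, n_steps)).astype(int))
    return grid[(grid >= n_min) & (grid <= n_max)]


def _fit_slope(ns: np.ndarray, fs: np.ndarray, lo: int, hi: int) -> tuple[float, float]:
    """OLS slope and R^2 of log10 F vs log10 n over box sizes in [lo, hi].

    Zero (or non-finite) fluctuations are excluded; fewer than 3 usable
    points flags the exponent undefined (nan).
    """
    sel = (ns >= lo) & (ns <= hi) & (fs > 0) & np.isfinite(fs)
    if sel.sum() < 3:
        return float("nan"), float("nan")
    lx = np.log10(ns[sel].astype(float))
    ly = np.log10(fs[sel])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def dfa_exponents(
    series: GlucoseSeries | np.ndarray,
    short_range: tuple[int, int] = DEFAULT_SHORT_RANGE,
    long_range: tuple[int, int] = DEFAULT_LONG_RANGE,
    min_box: int = DEFAULT_MIN_BOX,
) -> DFAResult:
    """F(n) curve plus the crossover-split exponents alpha1 and alpha2.

    Box sizes are evaluated on a log-spaced integer grid spanning
    [max(min_box, short_range[0]), min(long_range[1], floor(N/2))], with the
    crossover box size always included so it belongs to both fits.
    """
    values = series.values if isinstance(series, GlucoseSeries) else np.asarray(series, float)
    n_total = values.size
    if n_total < 2 * long_range[0]:
        raise ParameterError(
            f"series of {n_total} points too short for long-range minimum {long_range[0]}"
        )
    y = integrate_series(values)
    lo = max(min_box, short_range[0])
    hi = min(long_range[1], n_total // 2)
    grid = _log_grid(lo, hi)
    crossover = short_range[1]
    if lo <= crossover <= hi:
        grid = np.unique(np.append(grid, crossover))
    fs = np.array([fluctuation(y, int(n), min_box=min_box) for n in grid])
    a1, r2_1 = _fit_slope(grid, fs, max(min_box, short_range[0]), short_range[1])
    a2, r2_2 = _fit_slope(grid, fs, long_range[0], hi)
    return DFAResult(
        box_sizes=grid,
        fluctuations=fs,
        alpha1=a1,
        alpha2=a2,
        fit_range_short=(max(min_box, short_range[0]), short_range[1]),
        fit_range_long=(long_range[0], int(hi)),
        fit_r2_short=r2_1,
        fit_r2_long=r2_2,
    )


def scaling_exponent(
    values: np.ndarray, n_min: int = 16, n_max: int | None = None
) -> float:
    """Single-exponent DFA slope, used for calibration against fGn.

    Defaults fit log10 F vs log10 n over n in [16, min(512, N/4)]; the
    smallest boxes are excluded because first-order detrending is biased
    there, and boxes beyond N/4 average too few segments to be stable.
    """
    v = np.asarray(values, dtype=float)
    if n_max is None:
        n_max = min(512, v.size // 4)
    y = integrate_series(v)
    grid = _log_grid(n_min, n_max)
    fs = np.array([fluctuation(y, int(n)) for n in grid])
    slope, _ = _fit_slope(grid, fs, n_min, n_max)
    return slope
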