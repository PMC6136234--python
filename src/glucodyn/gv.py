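"""Conventional (linear) glycemia and glycemic-variability metrics.

Mean glucose, sample SD, %CV = 100*SD/mean, and time in a target range
(default 3.9-8.9 mmol/l, both bounds inclusive) expressed as hours per day.
The sample (n-1) standard deviation is used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glucodyn.errors import ComputationError, ParameterError
from glucodyn.series import GlucoseSeries

#: Default clinical target range, mmol/l (closed interval).
DEFAULT_RANGE = (3.9, 8.9)


@dataclass(frozen=True)
class GVMetrics:
    mean_glucose: float  # mmol/l
    sd: float  # mmol/l, sample (n-1) SD
    cv_percent: float  # 100 * sd / mean
    tir_hours_per_day: float
    n_total: int
    n_in_range: int
    range_low: float
    range_high: float


def time_in_range(
    series: GlucoseSeries,
    low: float = DEFAULT_RANGE[0],
    high: float = DEFAULT_RANGE[1],
) -> float:
    """Hours per day with glucose in the closed interval [low, high].

    tir = 24 * #{low <= v <= high} / n. Independent of the sampling
    interval because it is a fraction of samples scaled to a day.
    """
    if low >= high:
        raise ParameterError("need low < high for the target range")
    v = series.values
    if v.size == 0:
        raise ComputationError("empty series")
    in_range = np.count_nonzero((v >= low) & (v <= high))
    return 24.0 * in_range / v.size


def compute_gv(
    series: GlucoseSeries,
    low: float = DEFAULT_RANGE[0],
    high: float = DEFAULT_RANGE[1],
    per_day_average: bool = False,
) -> GVMetrics:
    """Mean, SD, %CV, and TIR over the supplied window.

    By default the metrics are computed once over the whole window (nominally
    48 h). With ``per_day_average=True`` mean/SD/%CV are computed per 24-h
    block and averaged — exposed because summary conventions differ between
    studies; block remainders shorter than 2 samples are dropped.
    """
    v = series.values
    if v.size < 2:
        raise ParameterError("need at least 2 samples")
    if per_day_average:
        per_day = max(1, int(round(24 * 60 / series.interval_min)))
        blocks = [v[i : i + per_day] for i in range(0, v.size, per_day)]
        blocks = [b for b in blocks if b.size >= 2]
        means = np.array([b.mean() for b in blocks])
        sds = np.array([b.std(ddof=1) for b in blocks])
        mean, sd = float(means.mean()), float(sds.mean())
        cv = float(np.mean(100.0 * sds / means))
    else:
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        if mean <= 0:
            raise ComputationError("non-positive mean glucose")
        cv = 100.0 * sd / mean
    if mean <= 0:
        raise ComputationError("non-positive mean glucose")
    n_in = int(np.count_nonzero((v >= low) & (v <= high)))
    return GVMetrics(
        mean_glucose=mean,
        sd=sd,
        cv_percent=cv,
        tir_hours_per_day=24.0 * n_in / v.size,
        n_total=int(v.size),
        n_in_range=n_in,
        range_low=low,
        range_high=high,
    )
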