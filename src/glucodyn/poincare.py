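"""Lagged Poincare plots of glucose series and their ellipse descriptors.

The plot pairs each glucose value with the value a fixed delay later:
(G(t), G(t+dt)). The point cloud is summarized by the dispersions across
(SD1) and along (SD2) the identity line, obtained as the SDs of the rotated
coordinates (x-y)/sqrt(2) and (x+y)/sqrt(2), plus the shape and area of the
fitting ellipse:

    SFE = SD2 / SD1        AFE = pi * SD1 * SD2

SD1 captures short-term (beat-to-beat, here sample-to-sample at the chosen
lag) variability, SD2 the longer-term excursions; an elongated cloud
(SFE >> 1) indicates strong correlation at the lag. The default delay is
60 min, the most informative of the probed 30/60/120-min delays for CGM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from glucodyn.errors import ParameterError
from glucodyn.series import GlucoseSeries

DEFAULT_LAG_MIN = 60.0


@dataclass(frozen=True)
class PoincareResult:
    lag_min: float
    lag_samples: int
    sd1: float  # mmol/l
    sd2: float  # mmol/l
    sfe: float  # dimensionless; nan when sd1 == 0 (flagged undefined)
    afe: float  # mmol^2/l^2
    n_pairs: int
    sfe_defined: bool = True


def ellipse_area(sd1: float, sd2: float) -> float:
    """Area of the fitting ellipse, AFE = pi * SD1 * SD2 (mmol^2/l^2)."""
    if sd1 < 0 or sd2 < 0:
        raise ParameterError("sd1 and sd2 must be >= 0")
    return math.pi * sd1 * sd2


def lagged_pairs(
    series: GlucoseSeries, lag_min: float = DEFAULT_LAG_MIN
) -> tuple[np.ndarray, np.ndarray]:
    """All overlapping pairs (G(t), G(t+dt)) at the requested delay.

    The delay must be a positive multiple of the sampling interval and
    shorter than the series.
    """
    if lag_min <= 0:
        raise ParameterError("lag must be positive")
    ratio = lag_min / series.interval_min
    lag = int(round(ratio))
    if abs(ratio - lag) > 1e-9 or lag == 0:
        raise ParameterError(
            f"lag {lag_min:g} min is not a multiple of the sampling interval "
            f"{series.interval_min:g} min"
        )
    if lag >= len(series):
        raise ParameterError("lag must be shorter than the series")
    v = series.values
    return v[:-lag], v[lag:]


def poincare_descriptors(
    series: GlucoseSeries,
    lag_min: float = DEFAULT_LAG_MIN,
    ddof: int = 1,
) -> PoincareResult:
    """SD1, SD2, SFE, AFE of the lagged Poincare plot.

    Uses sample (n-1) variance by default (``ddof=0`` is exposed because the
    population-variance convention also circulates). A constant series gives
    SD1 = SD2 = AFE = 0 with SFE flagged undefined (nan), not an exception.
    """
    x, y = lagged_pairs(series, lag_min)

    def _sd(u: np.ndarray) -> float:
        if np.ptp(u) == 0.0:  # exactly constant: avoid fp summation residue
            return 0.0
        return float(np.std(u / np.sqrt(2.0), ddof=ddof))

    sd1 = _sd(x - y)
    sd2 = _sd(x + y)
    if sd1 > 0:
        sfe, defined = sd2 / sd1, True
    else:
        sfe, defined = float("nan"), False
    lag = int(round(lag_min / series.interval_min))
    return PoincareResult(
        lag_min=lag_min,
        lag_samples=lag,
        sd1=sd1,
        sd2=sd2,
        sfe=sfe,
        afe=ellipse_area(sd1, sd2),
        n_pairs=x.size,
        sfe_defined=defined,
    )
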