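"""Sample entropy, coarse-graining, and the multiscale-entropy (MSE) index.

Sample entropy (SampEn) measures the irregularity of a series as the
negative log conditional probability that two sequences similar for m
points remain similar at the next point:

    SampEn(m, r) = -ln(A / B)

where B counts ordered template pairs (i != j) of length m within Chebyshev
distance r, A the same for length m+1, with self-matches excluded and
template start indices 0 .. N-m-1 for both lengths (the convention of the
standard multiscale-entropy tool chain, which this module reproduces
count-for-count).

Multiscale entropy evaluates SampEn on coarse-grained copies of the series
(non-overlapping window means at scales tau = 1..M) with the tolerance
r = r_factor * SD fixed from the original series; the complexity index is
the sum of the per-scale entropies. Defaults m=2, r_factor=0.15, M=5 — the
standard parameters for 576-point CGM traces, for which the coarsest scale
retains floor(576/5) = 115 samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from glucodyn.errors import ParameterError
from glucodyn.series import GlucoseSeries


@dataclass(frozen=True)
class MSEParams:
    m: int = 2
    r_factor: float = 0.15
    max_scale: int = 5

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError("template length m must be >= 1")
        if self.r_factor <= 0:
            raise ParameterError("r_factor must be positive")
        if self.max_scale < 1:
            raise ParameterError("max_scale must be >= 1")


@dataclass(frozen=True)
class MSEResult:
    params: MSEParams
    r_value: float  # realized tolerance, mmol/l
    sampen_by_scale: dict[int, float]  # nan marks an undefined scale
    complexity_index: float  # sum over defined scales
    coarse_lengths: dict[int, int]
    partial: bool = False  # True when any scale was undefined


def coarse_grain(values: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping window means at the given scale.

    output[j] = mean(values[j*tau .. j*tau + tau - 1]), j = 0..floor(N/tau)-1;
    the trailing remainder is discarded. Scale 1 is the identity.
    """
    v = np.asarray(values, dtype=float)
    if scale < 1:
        raise ParameterError("scale must be >= 1")
    if scale > v.size:
        raise ParameterError(f"scale {scale} exceeds series length {v.size}")
    n_out = v.size // scale
    return v[: n_out * scale].reshape(n_out, scale).mean(axis=1)


def sampen_counts(values: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Ordered template-match counts (A, B) for SampEn.

    B: pairs (i, j), i != j, with max_k |x[i+k]-x[j+k]| <= r for k < m;
    A: the same with the match extended to length m+1. Start indices run
    over 0..N-m-1 for both lengths, so A/B is a conditional probability.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ParameterError(f"need more than m+1={m + 1} samples, got {n}")
    if r <= 0:
        raise ParameterError("tolerance r must be positive")
    n_tpl = n - m
    within = np.ones((n_tpl, n_tpl), dtype=bool)
    for k in range(m):
        seg = x[k : k + n_tpl]
        within &= np.abs(seg[:, None] - seg[None, :]) <= r
    b = int(within.sum()) - n_tpl  # drop the diagonal self-matches
    seg = x[m : m + n_tpl]
    a = int((within & (np.abs(seg[:, None] - seg[None, :]) <= r)).sum()) - n_tpl
    return a, b


def sample_entropy(values: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) in nats; ``nan`` when no matches exist (undefined).

    ``r`` is the absolute tolerance in the units of ``values``; if omitted it
    defaults to 0.15 times the sample SD of ``values``.
    """
    x = np.asarray(values, dtype=float)
    if r is None:
        r = 0.15 * float(np.std(x, ddof=1))
    a, b = sampen_counts(x, m, r)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def mse_index(
    series: GlucoseSeries | np.ndarray, params: MSEParams = MSEParams()
) -> MSEResult:
    """Per-scale SampEn and the complexity index (their sum).

    The tolerance r = r_factor * SD is computed once from the original
    (scale-1) series and held fixed across scales, so the per-scale entropy
    profile reflects structure, not the variance shrinkage of averaging.
    An undefined entropy at any scale marks the whole index ``partial``;
    the index then sums the defined scales only.
    """
    values = series.values if isinstance(series, GlucoseSeries) else np.asarray(series, float)
    n = values.size
    min_len = params.max_scale * (params.m + 2)
    if n < min_len:
        raise ParameterError(
            f"need at least max_scale*(m+2) = {min_len} samples, got {n}"
        )
    r_value = params.r_factor * float(np.std(values, ddof=1))
    sampen: dict[int, float] = {}
    lengths: dict[int, int] = {}
    partial = False
    for scale in range(1, params.max_scale + 1):
        cg = coarse_grain(values, scale)
        lengths[scale] = cg.size
        if r_value == 0.0:
            # constant series: every template matches every other, A/B = 1
            sampen[scale] = 0.0
            continue
        s = sample_entropy(cg, m=params.m, r=r_value)
        sampen[scale] = s
        if math.isnan(s):
            partial = True
    defined = [s for s in sampen.values() if not math.isnan(s)]
    return MSEResult(
        params=params,
        r_value=r_value,
        sampen_by_scale=sampen,
        complexity_index=float(sum(defined)),
        coarse_lengths=lengths,
        partial=partial,
    )
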