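"""The in-memory container for one subject's CGM trace."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from glucodyn.errors import ParameterError

#: mg/dl per mmol/l (molar mass of glucose); glucose concentrations in this
#: package are mmol/l throughout.
MGDL_PER_MMOL = 18.016


@dataclass
class GlucoseSeries:
    """A uniformly sampled glucose trace in mmol/l.

    Parameters
    ----------
    subject_id
        Opaque identifier; uniqueness is enforced at the cohort level.
    values
        Glucose concentrations in mmol/l, one per sampling instant.
    interval_min
        Minutes between consecutive samples (5 for the emulated sensor).
    t0
        Optional ISO-8601 start timestamp. Analyses index by sample number,
        so a missing ``t0`` only affects CSV round-trips.
    group
        Optional cohort label (``ND``, ``T2D``, ``T1D``, or custom).
    meta
        Free-form annotations (clipping fraction, QC flags, generator
        provenance). Serialized as ``#``-prefixed comment lines by
        :mod:`glucodyn.cgm_io`.
    """

    subject_id: str
    values: np.ndarray
    interval_min: float = 5.0
    t0: str | None = None
    group: str | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ParameterError("a glucose series needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("glucose values must be finite")
        if np.any(self.values <= 0):
            raise ParameterError("glucose values must be positive (mmol/l)")
        if self.interval_min <= 0:
            raise ParameterError("sampling interval must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_hours(self) -> float:
        """Span covered by the samples, in hours."""
        return len(self) * self.interval_min / 60.0

    def times_min(self) -> np.ndarray:
        """Sample times in minutes from the start of the recording."""
        return np.arange(len(self), dtype=float) * self.interval_min

    def with_values(self, values: np.ndarray, **meta: Any) -> "GlucoseSeries":
        """Copy of this series with new values and extra meta entries."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return GlucoseSeries(
            subject_id=self.subject_id,
            values=np.asarray(values, dtype=float),
            interval_min=self.interval_min,
            t0=self.t0,
            group=self.group,
            meta=new_meta,
        )


def mgdl_to_mmol(values: np.ndarray | float) -> np.ndarray | float:
    """Convert mg/dl to mmol/l (division by 18.016)."""
    return np.asarray(values, dtype=float) / MGDL_PER_MMOL


def mmol_to_mgdl(values: np.ndarray | float) -> np.ndarray | float:
    """Convert mmol/l to mg/dl (multiplication by 18.016)."""
    return np.asarray(values, dtype=float) * MGDL_PER_MMOL
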