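"""Reading, writing, and quality-screening CGM series.

CSV dialect: comma-separated, ``.`` decimal, one header row, optional
``#``-prefixed comment lines before the header carrying series metadata as
``# key: value``. Columns written: ``subject_id, timestamp, glucose_mmol_l``
(glucose formatted to 4 decimal places). On read, a ``glucose_mgdl`` column
(or ``units="mgdl"``) is converted by division by 18.016. Timestamps are
optional; when absent a nominal 5-min grid is assumed and recorded in
``meta``.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from glucodyn.errors import FormatError, ParameterError, QCError
from glucodyn.series import GlucoseSeries, MGDL_PER_MMOL

#: Mean-absolute-difference threshold (%) of the manufacturer validity screen.
MAD_THRESHOLD_PERCENT = 28.0
#: Minimum number of paired sensor/meter readings for a valid recording.
MIN_PAIRED_READINGS = 3
#: Default longest gap (minutes) that may be filled by linear interpolation.
DEFAULT_MAX_GAP_MIN = 30.0


@dataclass(frozen=True)
class PairedReading:
    """One sensor/meter calibration pair used by the validity screen."""

    sensor_value: float  # mmol/l
    meter_value: float  # mmol/l
    time_offset_min: float = 0.0

    def __post_init__(self) -> None:
        if self.sensor_value <= 0 or self.meter_value <= 0:
            raise ParameterError("paired readings must be positive")


@dataclass(frozen=True)
class QCReport:
    passed: bool
    mad_percent: float
    n_pairs: int


def qc_validity(series: GlucoseSeries, paired: Iterable[PairedReading]) -> QCReport:
    """Manufacturer-style validity screen.

    Pass requires at least :data:`MIN_PAIRED_READINGS` sensor/meter pairs and
    a mean absolute difference ``100*mean(|sensor-meter|/meter)`` of at most
    :data:`MAD_THRESHOLD_PERCENT` percent.
    """
    pairs = list(paired)
    if any(p.meter_value == 0 for p in pairs):
        raise QCError("meter value of zero in paired readings")
    if pairs:
        mad = 100.0 * float(
            np.mean([abs(p.sensor_value - p.meter_value) / p.meter_value for p in pairs])
        )
    else:
        mad = float("nan")
    passed = len(pairs) >= MIN_PAIRED_READINGS and mad <= MAD_THRESHOLD_PERCENT
    return QCReport(passed=passed, mad_percent=mad, n_pairs=len(pairs))


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def write_cgm_csv(series: GlucoseSeries, path: str | Path | TextIO) -> None:
    """Write one series in the documented dialect (4-dp glucose values)."""
    own = isinstance(path, (str, Path))
    fh: TextIO = open(path, "w", encoding="utf-8") if own else path  # type: ignore[arg-type]
    try:
        fh.write(f"# subject_id: {series.subject_id}\n")
        fh.write(f"# interval_min: {series.interval_min:g}\n")
        if series.group is not None:
            fh.write(f"# group: {series.group}\n")
        if series.t0 is not None:
            fh.write(f"# t0: {series.t0}\n")
        for key, val in sorted(series.meta.items()):
            fh.write(f"# meta.{key}: {val}\n")
        fh.write("subject_id,timestamp,glucose_mmol_l\n")
        if series.t0 is not None:
            t0 = pd.Timestamp(series.t0)
            stamps = [
                (t0 + pd.Timedelta(minutes=i * series.interval_min)).isoformat()
                for i in range(len(series))
            ]
        else:
            stamps = ["" for _ in range(len(series))]
        for stamp, v in zip(stamps, series.values):
            fh.write(f"{series.subject_id},{stamp},{v:.4f}\n")
    finally:
        if own:
            fh.close()


def _parse_comments(lines: list[str]) -> dict:
    header: dict = {}
    meta: dict = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" not in body:
            continue
        key, val = body.split(":", 1)
        key, val = key.strip(), val.strip()
        if key.startswith("meta."):
            meta[key[5:]] = _coerce(val)
        else:
            header[key] = val
    header["meta"] = meta
    return header


def _coerce(val: str):
    low = val.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        f = float(val)
    except ValueError:
        return val
    return int(f) if f.is_integer() and "." not in val and "e" not in low else f


def read_cgm_csv(
    path: str | Path | TextIO,
    units: str = "auto",
    interval_min: float | None = None,
) -> GlucoseSeries:
    """Read one series written in the documented dialect.

    ``units`` may be ``"mmol"``, ``"mgdl"``, or ``"auto"`` (decide from the
    glucose column name; ``glucose_mmol_l`` vs ``glucose_mgdl``/``glucose_mg_dl``).
    Timestamps, when present, must be strictly increasing and equally spaced;
    when absent, a nominal grid of ``interval_min`` (default 5) is assumed.
    """
    own = isinstance(path, (str, Path))
    fh: TextIO = open(path, "r", encoding="utf-8") if own else path  # type: ignore[arg-type]
    try:
        text = fh.read()
    finally:
        if own:
            fh.close()
    comment_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    header = _parse_comments(comment_lines)
    df = pd.read_csv(_stdio.StringIO(text), comment="#")

    glucose_col = None
    col_units = None
    for col in df.columns:
        name = col.strip().lower()
        if name in ("glucose_mmol_l", "glucose_mmol"):
            glucose_col, col_units = col, "mmol"
        elif name in ("glucose_mgdl", "glucose_mg_dl"):
            glucose_col, col_units = col, "mgdl"
        elif name == "glucose" and glucose_col is None:
            glucose_col = col
    if glucose_col is None:
        raise FormatError("no glucose column found in header row")
    if units == "auto":
        if col_units is None:
            raise FormatError(
                "units not declared: name the column glucose_mmol_l/glucose_mgdl "
                "or pass units='mmol'|'mgdl'"
            )
        units = col_units
    if units not in ("mmol", "mgdl"):
        raise FormatError(f"unknown units {units!r}")

    values = df[glucose_col].to_numpy(dtype=float)
    if units == "mgdl":
        values = values / MGDL_PER_MMOL

    meta = dict(header.get("meta", {}))
    t0 = header.get("t0")
    iv = interval_min
    if "timestamp" in df.columns and df["timestamp"].notna().all() and len(df) and \
            str(df["timestamp"].iloc[0]).strip():
        stamps = pd.to_datetime(df["timestamp"])
        deltas = stamps.diff().dropna().dt.total_seconds().to_numpy() / 60.0
        if np.any(deltas <= 0):
            raise FormatError("timestamps are not strictly increasing")
        if iv is None:
            iv = float(np.median(deltas))
        t0 = stamps.iloc[0].isoformat()
    else:
        if iv is None:
            iv = float(header.get("interval_min", 5.0))
            if "interval_min" not in header:
                meta["assumed_interval_min"] = iv
    subject_id = header.get("subject_id")
    if subject_id is None and "subject_id" in df.columns and len(df):
        subject_id = str(df["subject_id"].iloc[0])
    return GlucoseSeries(
        subject_id=subject_id or "unknown",
        values=values,
        interval_min=float(iv),
        t0=t0,
        group=header.get("group"),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# gaps and windowing
# ---------------------------------------------------------------------------

def fill_gaps(
    series: GlucoseSeries,
    timestamps_min: np.ndarray | None = None,
    max_gap_min: float = DEFAULT_MAX_GAP_MIN,
) -> GlucoseSeries:
    """Linear interpolation of short gaps on the nominal sampling grid.

    ``timestamps_min`` gives the actual sample times in minutes from t0; when
    omitted the series is assumed gap-free and returned unchanged. Any gap
    longer than ``max_gap_min`` raises :class:`QCError` naming the gap;
    interpolated grid indices are recorded in ``meta['interpolated_indices']``.
    """
    if timestamps_min is None:
        return series
    t = np.asarray(timestamps_min, dtype=float)
    if t.size != len(series):
        raise ParameterError("timestamps_min must match the series length")
    if np.any(np.diff(t) <= 0):
        raise FormatError("timestamps are not strictly increasing")
    iv = series.interval_min
    gaps = np.diff(t)
    too_long = np.nonzero(gaps > max_gap_min)[0]
    if too_long.size:
        i = int(too_long[0])
        raise QCError(
            f"gap of {gaps[i]:g} min after t={t[i]:g} min exceeds max_gap_min={max_gap_min:g}"
        )
    grid = np.round((t - t[0]) / iv).astype(int)
    if np.any(np.abs(t - t[0] - grid * iv) > 1e-6 * iv + 1e-9):
        raise FormatError("timestamps do not align with the sampling grid")
    n_grid = int(grid[-1]) + 1
    full = np.interp(np.arange(n_grid) * iv, t - t[0], series.values)
    present = np.zeros(n_grid, dtype=bool)
    present[grid] = True
    interpolated = np.nonzero(~present)[0].tolist()
    if not interpolated:
        return series
    return series.with_values(full, interpolated_indices=interpolated)


def select_window(
    series: GlucoseSeries, n_points: int, position: str = "first"
) -> GlucoseSeries:
    """Fixed-length analysis window from a longer recording.

    ``position``: ``first`` (default), ``last``, or ``centered``. Recordings
    here are nominally longer than the 48-h/576-point analysis window; which
    sub-window is analysed is an explicit, recorded choice.
    """
    n = len(series)
    if n_points > n:
        raise ParameterError(f"window of {n_points} points exceeds series length {n}")
    if position == "first":
        start = 0
    elif position == "last":
        start = n - n_points
    elif position == "centered":
        start = (n - n_points) // 2
    else:
        raise ParameterError("position must be 'first', 'last', or 'centered'")
    return series.with_values(
        series.values[start : start + n_points], window_position=position, window_start=start
    )
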