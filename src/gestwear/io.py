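"""Recording I/O, wear-time accounting and day segmentation.

On-disk dialect
---------------
A recording is a plain CSV with header ``time_s,ax_g,ay_g,az_g``:
``time_s`` in seconds from the study origin (strictly increasing),
acceleration per axis in units of g.  Non-wear is represented by *absent*
rows, never by NaN.  The nominal sample rate (20 Hz for the wrist device
emulated here) is metadata supplied by the caller, not stored in the file.

Wear time is coverage-based: consecutive samples spaced at most
``max_gap_factor`` (default 2) nominal periods apart belong to one covered
run, and a run of samples ``t_0 .. t_k`` covers ``[t_0, t_k + 1/fs)``.  A
continuous 24 h recording therefore covers exactly 24 h.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError

RECORDING_COLUMNS = ("time_s", "ax_g", "ay_g", "az_g")
DAY_S = 86_400.0


@dataclasses.dataclass
class AccelerometerRecording:
    """Timestamped tri-axial acceleration (in g) for one patient.

    Parameters
    ----------
    patient_id:
        Identifier used in cohort tables.
    sample_rate_hz:
        Nominal sampling rate; gaps are judged relative to its period.
    time_s:
        Sample times in seconds from the study origin, strictly increasing.
    acc_g:
        Array of shape ``(n, 3)``: x, y, z acceleration in g.
    study_span_h:
        Total hours the patient was enrolled (monitoring-ratio denominator).
        Defaults to the data extent when not given.
    """

    patient_id: str
    sample_rate_hz: float
    time_s: np.ndarray
    acc_g: np.ndarray
    study_span_h: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        self.acc_g = np.asarray(self.acc_g, dtype=np.float64)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.acc_g.shape != (self.time_s.size, 3):
            raise ValueError(
                f"acc_g shape {self.acc_g.shape} does not match {self.time_s.size} samples"
            )
        if self.time_s.size > 1:
            bad = np.nonzero(np.diff(self.time_s) <= 0)[0]
            if bad.size:
                raise FormatError(f"time not strictly increasing at sample {bad[0] + 1}")

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    @property
    def period_s(self) -> float:
        return 1.0 / self.sample_rate_hz

    def span_h(self) -> float:
        """Enrollment span in hours: explicit study span, else data extent."""
        if self.study_span_h is not None:
            return float(self.study_span_h)
        if self.n_samples == 0:
            return 0.0
        return float((self.time_s[-1] + self.period_s) / 3600.0)


@dataclasses.dataclass(frozen=True)
class DaySegment:
    """One study-origin-relative 24 h block, half-open ``[d*86400, (d+1)*86400)``."""

    date_index: int
    start_idx: int
    stop_idx: int
    wear_h: float


def covered_runs(time_s: np.ndarray, sample_rate_hz: float, max_gap_factor: float = 2.0):
    """Split samples into gap-free runs.

    Returns a list of half-open index pairs ``(i0, i1)``; spacing larger than
    ``max_gap_factor / sample_rate_hz`` starts a new run.
    """
    n = len(time_s)
    if n == 0:
        return []
    max_dt = max_gap_factor / sample_rate_hz
    breaks = np.nonzero(np.diff(time_s) > max_dt)[0] + 1
    bounds = np.concatenate([[0], breaks, [n]])
    return [(int(bounds[k]), int(bounds[k + 1])) for k in range(len(bounds) - 1)]


def covered_spans(
    rec: AccelerometerRecording, max_gap_factor: float = 2.0
) -> np.ndarray:
    """Covered time intervals as an ``(k, 2)`` array of ``[start, end)`` seconds."""
    runs = covered_runs(rec.time_s, rec.sample_rate_hz, max_gap_factor)
    if not runs:
        return np.empty((0, 2))
    out = np.array(
        [[rec.time_s[i0], rec.time_s[i1 - 1] + rec.period_s] for i0, i1 in runs]
    )
    return out


def covered_time_s(rec: AccelerometerRecording, max_gap_factor: float = 2.0) -> float:
    spans = covered_spans(rec, max_gap_factor)
    return float(np.sum(spans[:, 1] - spans[:, 0])) if spans.size else 0.0


def compute_monitoring_ratio(
    rec: AccelerometerRecording,
    study_span_h: float | None = None,
    max_gap_factor: float = 2.0,
) -> float:
    """Hours with sensor data divided by hours enrolled, clamped to [0, 1].

    "Hours with data" is the summed covered time (see module docstring), so
    partial hours contribute pro rata.
    """
    span_h = study_span_h if study_span_h is not None else rec.study_span_h
    if span_h is None:
        span_h = rec.span_h()
    if span_h <= 0:
        raise InsufficientDataError("study span must be positive")
    ratio = covered_time_s(rec, max_gap_factor) / (span_h * 3600.0)
    return float(min(max(ratio, 0.0), 1.0))


def segment_by_day(
    rec: AccelerometerRecording,
    n_days: int | None = None,
    max_gap_factor: float = 2.0,
) -> list[DaySegment]:
    """Assign samples to study-origin-relative days and compute per-day wear.

    A sample at exactly ``t = d * 86400`` belongs to day ``d`` (half-open
    convention).  ``wear_h`` is the covered time intersected with the day.
    """
    if n_days is None:
        extent_s = rec.span_h() * 3600.0
        if rec.n_samples:
            extent_s = max(extent_s, rec.time_s[-1] + rec.period_s)
        n_days = max(1, math.ceil(extent_s / DAY_S - 1e-9))
    spans = covered_spans(rec, max_gap_factor)
    segments = []
    for d in range(n_days):
        lo, hi = d * DAY_S, (d + 1) * DAY_S
        i0 = int(np.searchsorted(rec.time_s, lo, side="left"))
        i1 = int(np.searchsorted(rec.time_s, hi, side="left"))
        wear = 0.0
        if spans.size:
            inter = np.minimum(spans[:, 1], hi) - np.maximum(spans[:, 0], lo)
            wear = float(np.sum(np.clip(inter, 0.0, None)))
        segments.append(DaySegment(d, i0, i1, wear / 3600.0))
    return segments


def read_recording(
    path: str | Path,
    patient_id: str | None = None,
    sample_rate_hz: float = 20.0,
    study_span_h: float | None = None,
) -> AccelerometerRecording:
    """Read a recording CSV, rejecting malformed rows with row-numbered errors.

    Row numbers in diagnostics are 1-based file lines (the header is line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from None
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    values = {}
    for col in RECORDING_COLUMNS:
        v = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=np.float64)
        bad = np.nonzero(~np.isfinite(v))[0]
        if bad.size:
            raise FormatError(f"{path}: malformed value in column {col} at row {bad[0] + 2}")
        values[col] = v
    t = values["time_s"]
    if t.size > 1:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise FormatError(f"{path}: time not strictly increasing at row {bad[0] + 3}")
    acc = np.column_stack([values["ax_g"], values["ay_g"], values["az_g"]])
    return AccelerometerRecording(
        patient_id=patient_id or path.stem,
        sample_rate_hz=sample_rate_hz,
        time_s=t,
        acc_g=acc,
        study_span_h=study_span_h,
    )


def write_recording(rec: AccelerometerRecording, path: str | Path) -> None:
    """Write the recording CSV (full-precision floats, exact round trip)."""
    df = pd.DataFrame(
        {
            "time_s": rec.time_s,
            "ax_g": rec.acc_g[:, 0],
            "ay_g": rec.acc_g[:, 1],
            "az_g": rec.acc_g[:, 2],
        }
    )
    df.to_csv(path, index=False)


def resample_to_nominal(rec: AccelerometerRecording) -> AccelerometerRecording:
    """Linearly interpolate onto the exact nominal-rate grid, per covered run.

    Gaps are preserved: no values are fabricated across non-wear.
    """
    fs = rec.sample_rate_hz
    times, axes = [], []
    for i0, i1 in covered_runs(rec.time_s, fs):
        t = rec.time_s[i0:i1]
        k0 = math.ceil(round(t[0] * fs, 9))
        k1 = math.floor(round(t[-1] * fs, 9))
        if k1 < k0:
            continue
        grid = np.arange(k0, k1 + 1) / fs
        times.append(grid)
        axes.append(
            np.column_stack([np.interp(grid, t, rec.acc_g[i0:i1, j]) for j in range(3)])
        )
    if not times:
        return AccelerometerRecording(
            rec.patient_id, fs, np.empty(0), np.empty((0, 3)), rec.study_span_h
        )
    return AccelerometerRecording(
        rec.patient_id,
        fs,
        np.concatenate(times),
        np.vstack(axes),
        rec.study_span_h,
    )
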