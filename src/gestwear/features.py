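"""Per-patient digital outcome measures.

Four features summarise a patient's recording: the activity-time ratio
(gait-involving time over monitored time), the median daily gesture count,
the aggregated gesture power (median over qualifying days of the per-day
median per-event power) and the monitoring ratio.  Days qualify when their
wear time reaches ``min_wear_h`` (default 8 h); a patient with no
qualifying data yields NaN (a missing-feature marker, deliberately not
zero).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from . import states
from .errors import InsufficientDataError
from .gesture import GestureEvent, daily_gesture_counts, events_to_frame
from .har import ActivityLabelSequence
from .io import AccelerometerRecording, DaySegment, compute_monitoring_ratio, covered_time_s, segment_by_day


@dataclasses.dataclass(frozen=True)
class PatientFeatureVector:
    patient_id: str
    activity_time_ratio: float
    median_daily_gesture_count: float
    gesture_power_agg: float
    monitoring_ratio: float
    n_days_used: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def activity_time_ratio(
    sample_code: np.ndarray, sample_rate_hz: float, monitored_time_s: float
) -> float:
    """Gait-involving time divided by total monitored (covered) time.

    Unclassified covered samples count in the denominator only.
    """
    if monitored_time_s <= 0:
        raise InsufficientDataError("monitored time must be positive")
    amb_s = float(np.sum(np.asarray(sample_code) == states.AMBULATORY)) / sample_rate_hz
    return amb_s / monitored_time_s


def median_daily_gesture_count(daily: pd.DataFrame, min_wear_h: float = 8.0) -> float:
    """Median of per-day counts over qualifying days; NaN when none qualify."""
    ok = daily[daily["wear_h"] >= min_wear_h]
    if len(ok) == 0:
        return math.nan
    return float(ok["count"].median())


def aggregate_gesture_power(
    events: list[GestureEvent] | pd.DataFrame,
    segments: list[DaySegment],
    min_wear_h: float = 8.0,
) -> float:
    """Median over qualifying days of the per-day median per-event power.

    Days qualify when wear reaches ``min_wear_h`` *and* hold at least one
    event; NaN when no day qualifies.
    """
    ev = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    if len(ev) == 0:
        return math.nan
    wear = {s.date_index: s.wear_h for s in segments}
    day = np.floor(ev["start_s"].to_numpy() / 86_400.0).astype(int)
    per_day = ev.assign(day=day).groupby("day")["power_g2"].median()
    per_day = per_day[[wear.get(d, 0.0) >= min_wear_h for d in per_day.index]]
    if len(per_day) == 0:
        return math.nan
    return float(per_day.median())


def build_feature_vector(
    rec: AccelerometerRecording,
    labels: ActivityLabelSequence,
    events: list[GestureEvent] | pd.DataFrame,
    min_wear_h: float = 8.0,
    study_span_h: float | None = None,
) -> PatientFeatureVector:
    """Assemble the full per-patient feature vector from pipeline outputs."""
    segments = segment_by_day(rec)
    daily = daily_gesture_counts(events, segments)
    monitored_s = covered_time_s(rec)
    return PatientFeatureVector(
        patient_id=rec.patient_id,
        activity_time_ratio=activity_time_ratio(labels.sample_code, rec.sample_rate_hz, monitored_s),
        median_daily_gesture_count=median_daily_gesture_count(daily, min_wear_h),
        gesture_power_agg=aggregate_gesture_power(events, segments, min_wear_h),
        monitoring_ratio=compute_monitoring_ratio(rec, study_span_h),
        n_days_used=int((daily["wear_h"] >= min_wear_h).sum()),
    )
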