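"""Movement segmentation and the three dependent variables.

Onset is the first sample where drawer speed exceeds 30 mm/s. Offset is
the first sample after onset where speed falls below 30 mm/s while the
drawer is within 35 mm of its maximum pullout position (the proximity
condition stops mid-movement pauses from terminating the trial). Peak
speed, movement time and the number of movement units (local speed
maxima between onset and offset) are computed on the filtered speed
series.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import Thresholds
from .containers import SpeedSeries, TrialFeatures

__all__ = [
    "NoMovementError",
    "TruncatedTrialError",
    "detect_onset",
    "detect_offset",
    "count_movement_units",
    "extract_features",
    "features_frame",
]


class NoMovementError(ValueError):
    """Speed never exceeds the onset threshold."""


class TruncatedTrialError(ValueError):
    """The offset condition is never met after onset."""


def detect_onset(series: SpeedSeries, v_on: float = 30.0) -> int:
    """Index of the first sample with speed strictly above ``v_on``."""
    if len(series.speed) == 0:
        raise ValueError("empty speed series")
    above = series.speed > v_on
    if not np.any(above):
        raise NoMovementError(f"speed never exceeds {v_on} mm/s")
    return int(np.argmax(above))


def detect_offset(series: SpeedSeries, onset: int, v_off: float = 30.0, d_max: float = 35.0) -> int:
    """First index after onset where speed drops below ``v_off`` within
    ``d_max`` mm of the maximum pullout position (first-match rule)."""
    if onset >= len(series.speed) - 1:
        raise TruncatedTrialError("onset at end of series")
    pullout = series.max_pullout
    tail = slice(onset + 1, None)
    hit = (series.speed[tail] < v_off) & (pullout - series.displacement[tail] < d_max)
    if not np.any(hit):
        raise TruncatedTrialError(
            f"speed never falls below {v_off} mm/s within {d_max} mm of max pullout"
        )
    return onset + 1 + int(np.argmax(hit))


def count_movement_units(
    series: SpeedSeries, onset: int, offset: int, min_prominence: float = 10.0
) -> int:
    """Number of local speed maxima on [onset, offset].

    A maximum is a sample strictly greater than its neighbours (plateaus
    collapse to one), retained only if its prominence within the window
    is at least ``min_prominence``; with a floor of 0 the literal
    local-maxima rule applies. The global maximum always counts, so the
    result is >= 1 even when the window's peak sits on its boundary.
    """
    if offset - onset < 2:
        raise ValueError("onset-offset window must span at least 3 samples")
    segment = series.speed[onset : offset + 1]
    peaks, _ = find_peaks(segment, prominence=min_prominence if min_prominence > 0 else None)
    return max(len(peaks), 1)


def extract_features(
    series: Optional[SpeedSeries],
    subject_id: str,
    age_group: str,
    trial: int,
    block: str,
    thresholds: Optional[Thresholds] = None,
    invalid_reason: Optional[str] = None,
) -> TrialFeatures:
    """All three dependent variables for one preprocessed trial.

    Detection failures set validity flags instead of raising. An
    onset/offset failure invalidates all three variables; a degenerate
    counting window invalidates only the unit count.
    """
    th = thresholds or Thresholds()
    feats = TrialFeatures(subject_id=subject_id, age_group=age_group, trial=trial, block=block)
    if series is None:
        feats.invalid_reason = invalid_reason or "preprocessing invalidated trial"
        return feats
    try:
        onset = detect_onset(series, th.v_on)
        offset = detect_offset(series, onset, th.v_off, th.d_max)
    except (NoMovementError, TruncatedTrialError) as exc:
        feats.invalid_reason = str(exc)
        return feats
    feats.onset_idx = onset
    feats.offset_idx = offset
    feats.peak_speed_mm_s = float(np.max(series.speed[onset : offset + 1]))
    feats.movement_time_ms = (offset - onset) / series.fs * 1000.0
    feats.valid_peak_speed = True
    feats.valid_movement_time = True
    try:
        feats.movement_units = float(count_movement_units(series, onset, offset, th.min_prominence))
        feats.valid_movement_units = True
    except ValueError as exc:
        feats.invalid_reason = str(exc)
    return feats


def features_frame(features: Iterable[TrialFeatures]) -> pd.DataFrame:
    """Tidy feature table, one row per trial."""
    cols = [
        "subject_id", "age_group", "trial", "block",
        "peak_speed_mm_s", "movement_time_ms", "movement_units",
        "valid_peak_speed", "valid_movement_time", "valid_movement_units",
    ]
    rows = [{c: getattr(f, c) for c in cols} for f in features]
    return pd.DataFrame(rows, columns=cols)
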