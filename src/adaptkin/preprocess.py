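"""Marker gap repair, low-pass filtering and differentiation to speed.

Repair order mirrors standard motion-capture practice: single-marker
gaps are reconstructed from the other marker plus the rigid offset
("pattern fill" -- both drawer markers keep a constant offset), then
both-marker gaps up to 500 samples are bridged with a cubic spline;
longer gaps invalidate the trial. Positions are then zero-phase
low-pass filtered (4th-order Butterworth, 8 Hz cutoff, forward-backward
so the two-pass attenuation at the cutoff is -6 dB) and differentiated
with central differences to scalar drawer speed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .config import Thresholds
from .containers import MarkerTrajectory, SpeedSeries

__all__ = [
    "UnrecoverableTrialError",
    "pattern_fill",
    "spline_fill",
    "lowpass",
    "compute_speed",
    "preprocess_trial",
]

#: Number of nearest both-present samples used to estimate the rigid offset.
PATTERN_FILL_WINDOW = 50


class UnrecoverableTrialError(ValueError):
    """No reference window exists from which to estimate the rigid offset."""


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as (start, stop) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def pattern_fill(traj: MarkerTrajectory, target_marker: str = "A") -> MarkerTrajectory:
    """Reconstruct missing samples of one marker from the other marker
    plus the rigid offset.

    The offset is the coordinate-wise median of (target - other) over
    the ``PATTERN_FILL_WINDOW`` both-present samples nearest to each
    gap, which is robust to sensor noise. Samples where both markers are
    missing are left for :func:`spline_fill`.
    """
    if target_marker not in {"A", "B"}:
        raise ValueError("target_marker must be 'A' or 'B'")
    out = traj.copy()
    out.hidden_truth = traj.hidden_truth
    tgt_pos, tgt_miss = (out.pos_a, out.missing_a) if target_marker == "A" else (out.pos_b, out.missing_b)
    oth_pos, oth_miss = (out.pos_b, out.missing_b) if target_marker == "A" else (out.pos_a, out.missing_a)

    fillable = tgt_miss & ~oth_miss
    if not np.any(fillable):
        return out
    both_present = np.flatnonzero(~tgt_miss & ~oth_miss)
    if len(both_present) == 0:
        raise UnrecoverableTrialError(
            f"trial {traj.subject_id}/{traj.trial}: no reference window with both markers present"
        )
    for start, stop in _runs(fillable):
        center = 0.5 * (start + stop - 1)
        nearest = both_present[np.argsort(np.abs(both_present - center), kind="stable")]
        window = nearest[: min(PATTERN_FILL_WINDOW, len(nearest))]
        offset = np.median(tgt_pos[window] - oth_pos[window], axis=0)
        tgt_pos[start:stop] = oth_pos[start:stop] + offset
        tgt_miss[start:stop] = False
    return out


def spline_fill(traj: MarkerTrajectory, max_gap: int = 500) -> MarkerTrajectory:
    """Bridge remaining gaps with a cubic spline through the flanking
    present samples, per marker and coordinate.

    A gap longer than ``max_gap`` samples, or one touching the trial
    boundary (no flank on one side), invalidates the trial rather than
    raising, so cohorts containing unusable trials still process.
    """
    out = traj.copy()
    out.hidden_truth = traj.hidden_truth
    for pos, miss in ((out.pos_a, out.missing_a), (out.pos_b, out.missing_b)):
        if not np.any(miss):
            continue
        for start, stop in _runs(miss):
            if stop - start > max_gap:
                out.valid = False
                out.invalid_reason = f"gap of {stop - start} samples exceeds spline limit {max_gap}"
                return out
            if start == 0 or stop == out.n_samples:
                out.valid = False
                out.invalid_reason = "gap touches trial boundary; spline fill would extrapolate"
                return out
        present = np.flatnonzero(~miss)
        spline = CubicSpline(out.t[present], pos[present], axis=0)  # not-a-knot: exact on cubics
        gap_idx = np.flatnonzero(miss)
        pos[gap_idx] = spline(out.t[gap_idx])
        miss[:] = False
    return out


def lowpass(traj: MarkerTrajectory, fc_hz: float = 8.0, order: int = 4) -> MarkerTrajectory:
    """Zero-phase Butterworth low-pass of both markers' coordinates.

    Applied forward-backward (``filtfilt``), so the effective magnitude
    response is the squared single-pass response: -6 dB at the cutoff.
    """
    if fc_hz >= traj.fs / 2:
        raise ValueError(f"cutoff {fc_hz} Hz must be below Nyquist ({traj.fs / 2} Hz)")
    if np.any(traj.missing_a) or np.any(traj.missing_b):
        raise ValueError("trajectory still has missing samples; fill gaps before filtering")
    b, a = butter(order, fc_hz, fs=traj.fs)
    out = traj.copy()
    out.hidden_truth = traj.hidden_truth
    out.pos_a = filtfilt(b, a, traj.pos_a, axis=0)
    out.pos_b = filtfilt(b, a, traj.pos_b, axis=0)
    return out


def compute_speed(traj: MarkerTrajectory) -> SpeedSeries:
    """Differentiate the front marker to scalar drawer speed.

    Speed is the Euclidean norm of the central-difference derivative
    (one-sided at the endpoints) of the front marker's position;
    displacement is the norm of position minus the trial-start position,
    which equals pull-axis excursion for a drawer moving along one axis.
    """
    if traj.n_samples < 3:
        raise ValueError("at least 3 samples are required to differentiate")
    if np.any(traj.missing_a):
        raise ValueError("front marker has missing samples")
    vel = np.gradient(traj.pos_a, traj.t, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    displacement = np.linalg.norm(traj.pos_a - traj.pos_a[0], axis=1)
    return SpeedSeries(
        t=traj.t, speed=speed, displacement=displacement, fs=traj.fs,
        subject_id=traj.subject_id, trial=traj.trial,
    )


def preprocess_trial(traj: MarkerTrajectory, thresholds: Optional[Thresholds] = None) -> tuple[Optional[SpeedSeries], MarkerTrajectory]:
    """Full repair-filter-differentiate chain for one trial.

    Returns ``(speed_series, repaired_trajectory)``; the speed series is
    None when the trial was invalidated (oversized gap, boundary gap, or
    unrecoverable markers), with the reason recorded on the trajectory.
    """
    th = thresholds or Thresholds()
    try:
        repaired = pattern_fill(traj, "A")
        repaired = pattern_fill(repaired, "B")
    except UnrecoverableTrialError as exc:
        out = traj.copy()
        out.valid = False
        out.invalid_reason = str(exc)
        return None, out
    repaired = spline_fill(repaired, max_gap=th.max_gap)
    if not repaired.valid:
        return None, repaired
    filtered = lowpass(repaired, fc_hz=th.fc_hz, order=th.filter_order)
    # Zero-phase filtering leaves a noisy derivative transient at the trial
    # boundaries; cut a fixed margin (the recordings pad the movement) so
    # event detection never sees it.
    k = int(round(th.edge_trim_s * filtered.fs))
    if k > 0 and filtered.n_samples > 2 * k + 10:
        filtered = MarkerTrajectory(
            t=filtered.t[k:-k], pos_a=filtered.pos_a[k:-k], pos_b=filtered.pos_b[k:-k],
            fs=filtered.fs, subject_id=filtered.subject_id, trial=filtered.trial,
        )
    return compute_speed(filtered), filtered
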