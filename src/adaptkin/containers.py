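"""Core data containers shared across the pipeline stages.

Conventions: positions in mm, time in seconds, speeds in mm/s, movement
time in ms. Trials are numbered 1..36; trials 1-2 are warm-up, 3-12
baseline, 13-24 adaptation (increased drawer resistance), 25-36
deadaptation (resistance back to baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Tidy feature-table column per dependent variable.
VARIABLES = ("peak_speed_mm_s", "movement_time_ms", "movement_units")

#: Age-group labels, youngest first.
AGE_GROUPS = ("1.5yo", "3yo", "adult")


@dataclass(frozen=True)
class BlockDesign:
    """Assignment of the 36 trials to experimental blocks.

    Default layout: warm-up 1-2, baseline 3-12, adaptation 13-24,
    deadaptation 25-36. Indices must be contiguous, disjoint and cover
    1..36.
    """

    warmup: tuple[int, ...] = tuple(range(1, 3))
    baseline: tuple[int, ...] = tuple(range(3, 13))
    adaptation: tuple[int, ...] = tuple(range(13, 25))
    deadaptation: tuple[int, ...] = tuple(range(25, 37))

    def __post_init__(self) -> None:
        blocks = [self.warmup, self.baseline, self.adaptation, self.deadaptation]
        all_idx = [i for b in blocks for i in b]
        if sorted(all_idx) != list(range(1, len(all_idx) + 1)):
            raise ValueError("block indices must be disjoint and cover 1..n contiguously")
        for b in blocks:
            if list(b) != list(range(b[0], b[-1] + 1)):
                raise ValueError("each block must be a contiguous trial range")

    @property
    def n_trials(self) -> int:
        return len(self.warmup) + len(self.baseline) + len(self.adaptation) + len(self.deadaptation)

    def block_of(self, trial: int) -> str:
        for name in ("warmup", "baseline", "adaptation", "deadaptation"):
            if trial in getattr(self, name):
                return name
        raise ValueError(f"trial {trial} outside design (1..{self.n_trials})")

    @property
    def first_adaptation(self) -> int:
        return self.adaptation[0]

    @property
    def first_deadaptation(self) -> int:
        return self.deadaptation[0]

    @property
    def last3_adaptation(self) -> tuple[int, ...]:
        return self.adaptation[-3:]

    @property
    def last3_deadaptation(self) -> tuple[int, ...]:
        return self.deadaptation[-3:]


@dataclass
class MarkerTrajectory:
    """Two-marker drawer kinematics for one trial at a fixed sampling rate.

    ``pos_a`` is the front-edge marker that defines drawer speed;
    ``pos_b`` is the lateral marker used for rigid-offset gap repair.
    Missing samples are NaN in the position arrays and True in the
    corresponding mask. ``hidden_truth`` optionally retains the original
    positions before gaps were injected (synthetic data only), for
    recovery testing.
    """

    t: np.ndarray
    pos_a: np.ndarray
    pos_b: np.ndarray
    fs: float
    missing_a: np.ndarray = field(default=None)  # type: ignore[assignment]
    missing_b: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str = ""
    trial: int = 0
    valid: bool = True
    invalid_reason: Optional[str] = None
    hidden_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos_a = np.asarray(self.pos_a, dtype=float)
        self.pos_b = np.asarray(self.pos_b, dtype=float)
        n = len(self.t)
        if self.pos_a.shape != (n, 3) or self.pos_b.shape != (n, 3):
            raise ValueError("pos_a/pos_b must have shape (n, 3) matching t")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.missing_a is None:
            self.missing_a = np.zeros(n, dtype=bool)
        if self.missing_b is None:
            self.missing_b = np.zeros(n, dtype=bool)
        self.missing_a = np.asarray(self.missing_a, dtype=bool)
        self.missing_b = np.asarray(self.missing_b, dtype=bool)
        if self.missing_a.shape != (n,) or self.missing_b.shape != (n,):
            raise ValueError("missing masks must match length of t")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def copy(self) -> "MarkerTrajectory":
        return replace(
            self,
            t=self.t.copy(),
            pos_a=self.pos_a.copy(),
            pos_b=self.pos_b.copy(),
            missing_a=self.missing_a.copy(),
            missing_b=self.missing_b.copy(),
            hidden_truth=None if self.hidden_truth is None else dict(self.hidden_truth),
        )


@dataclass
class SpeedSeries:
    """Scalar drawer speed and pull-axis displacement for one trial."""

    t: np.ndarray
    speed: np.ndarray
    displacement: np.ndarray
    fs: float
    subject_id: str = ""
    trial: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if not (len(self.t) == len(self.speed) == len(self.displacement)):
            raise ValueError("t, speed and displacement must have equal length")

    @property
    def max_pullout(self) -> float:
        return float(np.max(self.displacement))


@dataclass
class TrialFeatures:
    """The three dependent variables for one trial, with validity flags.

    Detection failures (no movement, truncated trial, upstream
    invalidation) set the validity flags rather than raising, so cohorts
    containing unusable trials still process end to end.
    """

    subject_id: str
    age_group: str
    trial: int
    block: str
    peak_speed_mm_s: float = np.nan
    movement_time_ms: float = np.nan
    movement_units: float = np.nan
    valid_peak_speed: bool = False
    valid_movement_time: bool = False
    valid_movement_units: bool = False
    onset_idx: int = -1
    offset_idx: int = -1
    invalid_reason: Optional[str] = None
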