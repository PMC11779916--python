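"""Synthetic drawer-opening cohorts with known ground truth.

Each trial's speed profile is a superposition of minimum-jerk
submovements: a main pull plus 0-3 smaller corrective pulses, the
standard description of bell-shaped point-to-point movements and of the
multi-peaked profiles young children produce. Trials are targeted at a
per-trial (peak speed, movement time, unit count) triple drawn from
age-group dynamics:

* baseline trials scatter log-normally around a subject-level mean;
* at the first adaptation trial peak speed drops by a fixed fraction
  (25% by default, matching the printed group-level drop from
  ~355 mm/s to ~266 mm/s) and recovers exponentially over trials;
* movement time is perturbed upward by an age-specific fraction that
  decays with the same time constant, calibrated so the ground-truth
  linear slopes over the adaptation block equal the printed -33.6 /
  -21.2 / -10.1 ms/trial (1.5yo / 3yo / adults);
* at the first deadaptation trial peak speed overshoots (aftereffect)
  and movement time undershoots, both decaying exponentially.

The construction places corrective submovements so that inter-pulse
speed dips stay well above the 30 mm/s offset threshold, and rescales
time and amplitude jointly so the analytic onset-offset movement time
and the peak speed match their targets exactly. Ground-truth features
are stored alongside the emitted trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import AGE_GROUPS, BlockDesign, MarkerTrajectory

__all__ = [
    "SubmovementSpec",
    "AgeGroupParams",
    "SubjectRecord",
    "Gap",
    "min_jerk_speed",
    "min_jerk_displacement",
    "build_trial_submovements",
    "generate_trial",
    "generate_subject",
    "generate_cohort",
    "inject_gaps",
    "default_age_params",
    "cohort_to_long_frame",
]

#: Pull axis of the drawer in the lab frame.
PULL_AXIS = np.array([1.0, 0.0, 0.0])

#: Rigid offset of the lateral lower-edge marker from the front marker, mm.
MARKER_OFFSET = np.array([-35.0, -280.0, -120.0])

#: Stationary padding before/after the movement, s.
LEAD_IN_S = 0.4
LEAD_OUT_S = 0.4

# Corrective-submovement geometry (relative to the main pull).
_CORRECTIVE_AMP_FRAC = 0.20
_CORRECTIVE_DUR_FRAC = 0.50
#: Inter-pulse speed dips are capped from below at this level so a trial
#: always forms a single onset-offset envelope (well above the 30 mm/s
#: offset threshold even under sensor noise).
_DIP_FLOOR_MM_S = 45.0
_DIP_PEAK_FRAC = 0.18


@dataclass(frozen=True)
class SubmovementSpec:
    """One bell-shaped (minimum-jerk) speed pulse."""

    amplitude_mm: float
    duration_s: float
    start_s: float

    def __post_init__(self) -> None:
        if self.amplitude_mm <= 0:
            raise ValueError("submovement amplitude must be positive")
        if self.duration_s <= 0:
            raise ValueError("submovement duration must be positive")
        if self.start_s < 0:
            raise ValueError("submovement start time must be >= 0")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def peak_speed(self) -> float:
        return 1.875 * self.amplitude_mm / self.duration_s


def min_jerk_speed(amplitude_mm: float, duration_s: float, t: np.ndarray | float) -> np.ndarray | float:
    """Speed of a minimum-jerk submovement of amplitude D over duration T.

    v(t) = (D/T) * (30 tau^2 - 60 tau^3 + 30 tau^4), tau = t/T, and 0
    outside [0, T]. Peak speed is 1.875 D/T at tau = 1/2.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    tau = np.clip(np.asarray(t, dtype=float) / duration_s, 0.0, 1.0)
    v = (amplitude_mm / duration_s) * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    return v if np.ndim(t) else float(v)


def min_jerk_displacement(amplitude_mm: float, duration_s: float, t: np.ndarray | float) -> np.ndarray | float:
    """Displacement D * (10 tau^3 - 15 tau^4 + 6 tau^5), clamped to [0, D]."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    tau = np.clip(np.asarray(t, dtype=float) / duration_s, 0.0, 1.0)
    s = amplitude_mm * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return s if np.ndim(t) else float(s)


def pulse_train_speed(specs: Sequence[SubmovementSpec], t: np.ndarray) -> np.ndarray:
    """Total speed of a superposition of submovements at times ``t``."""
    v = np.zeros_like(np.asarray(t, dtype=float))
    for sp in specs:
        v = v + min_jerk_speed(sp.amplitude_mm, sp.duration_s, np.asarray(t) - sp.start_s)
    return v


def pulse_train_displacement(specs: Sequence[SubmovementSpec], t: np.ndarray) -> np.ndarray:
    s = np.zeros_like(np.asarray(t, dtype=float))
    for sp in specs:
        s = s + min_jerk_displacement(sp.amplitude_mm, sp.duration_s, np.asarray(t) - sp.start_s)
    return s


@dataclass(frozen=True)
class AgeGroupParams:
    """Generative parameters of one age group.

    Baseline means and between-subject SDs come from the printed group
    means and standard errors (SD = SE * sqrt(n)); the movement-time
    trial-to-trial CVs are the printed per-group values. Perturbation
    fractions and time constants realize the printed trial-13 peak-speed
    drop and the printed per-age movement-time adaptation slopes; the
    deadaptation overshoot fractions come from the printed first
    deadaptation trial vs baseline ratios.
    """

    label: str
    baseline_peak_speed_mean: float
    baseline_peak_speed_sd: float
    baseline_movement_time_mean: float
    baseline_movement_time_sd: float
    baseline_units_distribution: tuple[float, ...]
    perturbation_fraction: float = 0.25
    adapt_tau: float = 2.0
    aftereffect_fraction: float = 0.185
    deadapt_tau: float = 2.0
    mt_perturbation_fraction: float = 0.25
    mt_aftereffect_fraction: float = 0.131
    mt_trial_cv: float = 0.2
    speed_trial_cv: float = 0.15
    noise_sd: float = 0.3
    weight_g: float = 0.0  # perturbation weight, metadata only

    def __post_init__(self) -> None:
        p = np.asarray(self.baseline_units_distribution, dtype=float)
        if p.ndim != 1 or len(p) != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("units distribution must be 4 probabilities summing to 1")
        if not 0 <= self.perturbation_fraction < 1:
            raise ValueError("perturbation_fraction must be in [0, 1)")
        if self.adapt_tau <= 0 or self.deadapt_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_age_params() -> dict[str, AgeGroupParams]:
    """Study-calibrated defaults for the three age groups."""
    return {
        "1.5yo": AgeGroupParams(
            label="1.5yo",
            baseline_peak_speed_mean=388.22,
            baseline_peak_speed_sd=25.75 * np.sqrt(19),
            baseline_movement_time_mean=1052.34,
            baseline_movement_time_sd=84.54 * np.sqrt(19),
            baseline_units_distribution=(0.60, 0.30, 0.06, 0.04),
            adapt_tau=4.0,
            deadapt_tau=4.0,
            mt_perturbation_fraction=0.4076,
            mt_trial_cv=0.375,
            speed_trial_cv=0.20,
            weight_g=150.0,
        ),
        "3yo": AgeGroupParams(
            label="3yo",
            baseline_peak_speed_mean=303.10,
            baseline_peak_speed_sd=15.15 * np.sqrt(19),
            baseline_movement_time_mean=1152.61,
            baseline_movement_time_sd=60.24 * np.sqrt(19),
            baseline_units_distribution=(0.64, 0.28, 0.06, 0.02),
            adapt_tau=2.5,
            deadapt_tau=2.5,
            mt_perturbation_fraction=0.2452,
            mt_trial_cv=0.302,
            speed_trial_cv=0.15,
            weight_g=250.0,
        ),
        "adult": AgeGroupParams(
            label="adult",
            baseline_peak_speed_mean=360.47,
            baseline_peak_speed_sd=11.36 * np.sqrt(20),
            baseline_movement_time_mean=831.72,
            baseline_movement_time_sd=25.09 * np.sqrt(20),
            baseline_units_distribution=(1.0, 0.0, 0.0, 0.0),
            adapt_tau=1.0,
            deadapt_tau=1.0,
            mt_perturbation_fraction=0.2232,
            mt_trial_cv=0.113,
            speed_trial_cv=0.10,
            weight_g=500.0,
        ),
    }


# ---------------------------------------------------------------------------
# trial construction
# ---------------------------------------------------------------------------

def _dip_between(specs: Sequence[SubmovementSpec], t_lo: float, t_hi: float, n: int = 400) -> float:
    """Minimum total speed on [t_lo, t_hi] (fine grid scan)."""
    tg = np.linspace(t_lo, t_hi, n)
    return float(np.min(pulse_train_speed(specs, tg)))


def _append_corrective(specs: list[SubmovementSpec], amp: float, dur: float, dip_target: float) -> None:
    """Append a corrective pulse whose inter-pulse dip equals ``dip_target``.

    The dip is a monotone decreasing function of the pulse start time, so
    bisection on the start time within the previous pulse's tail finds
    the placement. If even a fully-overlapped start cannot reach the
    target the pulse is placed at maximum overlap (dip above target).
    """
    prev = specs[-1]
    lo = prev.start_s + 0.5 * prev.duration_s  # start at previous peak: no dip at all
    hi = prev.end_s + 0.25 * dur               # essentially detached: deep dip
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        trial = specs + [SubmovementSpec(amp, dur, mid)]
        t_peak_prev = prev.start_s + 0.5 * prev.duration_s
        t_peak_new = mid + 0.5 * dur
        dip = _dip_between(trial, t_peak_prev, t_peak_new)
        if dip > dip_target:
            lo = mid
        else:
            hi = mid
    specs.append(SubmovementSpec(amp, dur, 0.5 * (lo + hi)))


def _analytic_movement_time(
    specs: Sequence[SubmovementSpec], v_on: float = 30.0, v_off: float = 30.0, d_max: float = 35.0
) -> tuple[float, float, float]:
    """Onset/offset times of a noise-free pulse train on a fine grid.

    Onset: first time speed exceeds ``v_on``. Offset: first time after
    onset where speed falls below ``v_off`` while displacement is within
    ``d_max`` of the final pullout. Returns (t_on, t_off, mt_s).
    """
    t_end = max(sp.end_s for sp in specs)
    tg = np.linspace(0.0, t_end, max(4000, int(t_end * 4000)))
    v = pulse_train_speed(specs, tg)
    s = pulse_train_displacement(specs, tg)
    total = float(sum(sp.amplitude_mm for sp in specs))
    above = v > v_on
    if not np.any(above):
        raise ValueError("pulse train never exceeds onset threshold")
    i_on = int(np.argmax(above))
    after = np.flatnonzero((v[i_on:] < v_off) & (total - s[i_on:] < d_max)) + i_on
    if len(after) == 0:
        raise ValueError("pulse train never satisfies offset rule")
    i_off = int(after[0])
    return float(tg[i_on]), float(tg[i_off]), float(tg[i_off] - tg[i_on])


@lru_cache(maxsize=256)
def _normalized_train(n_units: int, dip_ratio: float) -> tuple[SubmovementSpec, ...]:
    """Unit-amplitude, unit-duration main pull plus placed correctives.

    ``dip_ratio`` is the inter-pulse dip as a fraction of the train's
    peak speed (1.875 in normalized units).
    """
    specs = [SubmovementSpec(1.0, 1.0, 0.0)]
    for _ in range(n_units - 1):
        _append_corrective(
            specs, _CORRECTIVE_AMP_FRAC, _CORRECTIVE_DUR_FRAC, dip_ratio * 1.875
        )
    return tuple(specs)


def build_trial_submovements(
    peak_speed: float,
    movement_time_ms: float,
    n_units: int,
    v_on: float = 30.0,
    v_off: float = 30.0,
    d_max: float = 35.0,
) -> list[SubmovementSpec]:
    """Construct a pulse train with exact target peak speed and analytic
    onset-offset movement time, carrying ``n_units`` speed maxima.

    The main pull is followed by ``n_units - 1`` corrective pulses at
    20% amplitude and 50% duration, placed so inter-pulse dips sit at
    max(45 mm/s, 18% of peak). The whole train is then scaled jointly in
    time and amplitude (speed-preserving) to match the target movement
    time.
    """
    if peak_speed <= max(v_on, v_off):
        raise ValueError("target peak speed must exceed the event thresholds")
    if movement_time_ms <= 0:
        raise ValueError("movement time must be positive")
    if not 1 <= n_units <= 4:
        raise ValueError("unit count must be in 1..4")

    # Normalized template (unit amplitude/duration main pull); the dip
    # placement depends only on the dip-to-peak ratio, so it is cached.
    dip_ratio = round(max(_DIP_FLOOR_MM_S / peak_speed, _DIP_PEAK_FRAC), 3)
    amp_scale = peak_speed / 1.875
    specs = [
        SubmovementSpec(sp.amplitude_mm * amp_scale, sp.duration_s, sp.start_s)
        for sp in _normalized_train(n_units, dip_ratio)
    ]

    _, _, mt_s = _analytic_movement_time(specs, v_on, v_off, d_max)
    scale = (movement_time_ms / 1000.0) / mt_s
    # Time-and-amplitude scaling leaves every speed value unchanged while
    # scaling all durations (hence the measured movement time) by `scale`.
    return [
        SubmovementSpec(sp.amplitude_mm * scale, sp.duration_s * scale, sp.start_s * scale)
        for sp in specs
    ]


def generate_trial(
    specs: Sequence[SubmovementSpec],
    fs: float = 100.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    lead_in_s: float = LEAD_IN_S,
    lead_out_s: float = LEAD_OUT_S,
    marker_offset: np.ndarray = MARKER_OFFSET,
    subject_id: str = "",
    trial: int = 0,
) -> MarkerTrajectory:
    """Emit a two-marker trajectory for a submovement train.

    The train's speed is integrated (in closed form) to displacement
    along the pull axis; both markers ride rigidly on the drawer, and
    i.i.d. Gaussian position noise of SD ``noise_sd`` mm is added per
    marker and coordinate.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if not specs:
        raise ValueError("at least one submovement is required")
    if noise_sd > 0 and rng is None:
        raise ValueError("rng is required when noise_sd > 0")

    t_move_end = max(sp.end_s for sp in specs)
    n = int(np.ceil((lead_in_s + t_move_end + lead_out_s) * fs)) + 1
    t = np.arange(n) / fs
    disp = pulse_train_displacement(specs, t - lead_in_s)
    pos_a = disp[:, None] * PULL_AXIS[None, :]
    pos_b = pos_a + np.asarray(marker_offset, dtype=float)[None, :]
    if noise_sd > 0:
        pos_a = pos_a + rng.normal(0.0, noise_sd, pos_a.shape)
        pos_b = pos_b + rng.normal(0.0, noise_sd, pos_b.shape)
    return MarkerTrajectory(t=t, pos_a=pos_a, pos_b=pos_b, fs=fs, subject_id=subject_id, trial=trial)


# ---------------------------------------------------------------------------
# subject and cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """Raw trials plus per-trial ground truth for one synthetic subject."""

    subject_id: str
    age_group: str
    params: AgeGroupParams
    design: BlockDesign
    trials: list[MarkerTrajectory]
    ground_truth: pd.DataFrame
    seed_entropy: int


def _dynamics_factors(params: AgeGroupParams, design: BlockDesign, trial: int) -> tuple[float, float]:
    """Noise-free (speed, movement-time) multipliers for one trial."""
    block = design.block_of(trial)
    if block == "adaptation":
        k = trial - design.first_adaptation  # 0-based within block
        e = np.exp(-k / params.adapt_tau)
        return 1.0 - params.perturbation_fraction * e, 1.0 + params.mt_perturbation_fraction * e
    if block == "deadaptation":
        k = trial - design.first_deadaptation
        e = np.exp(-k / params.deadapt_tau)
        return 1.0 + params.aftereffect_fraction * e, 1.0 - params.mt_aftereffect_fraction * e
    return 1.0, 1.0


def generate_subject(
    params: AgeGroupParams,
    design: Optional[BlockDesign] = None,
    seed: Optional[int | np.random.SeedSequence] = None,
    fs: float = 100.0,
    subject_id: str = "",
    noise_sd: Optional[float] = None,
) -> SubjectRecord:
    """Generate all trials of one subject with stored ground truth.

    A subject-level baseline (peak speed, movement time) is drawn from
    the group distribution; each trial multiplies it by the block
    dynamics factor and a mean-one log-normal trial fluctuation whose
    log-SD is the group's trial-to-trial CV. The submovement count is
    drawn from the group's unit distribution, with one extra unit forced
    on the first perturbed trial (the corrective response to the
    unexpected resistance).
    """
    if seed is None:
        raise ValueError("a seed is required: subject generation must be reproducible")
    if design is None:
        design = BlockDesign()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    noise = params.noise_sd if noise_sd is None else noise_sd

    # Subject-level baseline, guarded away from degenerate draws.
    base_v = max(rng.normal(params.baseline_peak_speed_mean, params.baseline_peak_speed_sd),
                 0.35 * params.baseline_peak_speed_mean)
    base_mt = max(rng.normal(params.baseline_movement_time_mean, params.baseline_movement_time_sd),
                  0.35 * params.baseline_movement_time_mean)

    p_units = np.asarray(params.baseline_units_distribution)
    rows = []
    trials = []
    for trial in range(1, design.n_trials + 1):
        d_v, d_m = _dynamics_factors(params, design, trial)
        eps_v = rng.lognormal(-0.5 * params.speed_trial_cv**2, params.speed_trial_cv) if params.speed_trial_cv > 0 else 1.0
        eps_m = rng.lognormal(-0.5 * params.mt_trial_cv**2, params.mt_trial_cv) if params.mt_trial_cv > 0 else 1.0
        target_v = base_v * d_v * eps_v
        target_mt = base_mt * d_m * eps_m
        n_units = int(rng.choice(4, p=p_units)) + 1
        if design.block_of(trial) == "adaptation":
            # Corrective-submovement elevation: certain on the first
            # perturbed trial, decaying with the adaptation time constant
            # (units rise at perturbation onset, then fall back).
            k = trial - design.first_adaptation
            if rng.random() < np.exp(-k / params.adapt_tau):
                n_units = min(n_units + 1, 4)
        # A corrective submovement occupies ~300 ms; a fast trial cannot
        # physically carry several (and the 8 Hz filter would merge them).
        n_units = min(n_units, 1 + int(max(0.0, target_mt - 300.0) // 300.0))
        n_units = max(n_units, 1)
        specs = build_trial_submovements(target_v, target_mt, n_units)
        traj = generate_trial(specs, fs=fs, noise_sd=noise, rng=rng, subject_id=subject_id, trial=trial)
        trials.append(traj)
        rows.append(
            {
                "subject_id": subject_id,
                "age_group": params.label,
                "trial": trial,
                "block": design.block_of(trial),
                "true_peak_speed_mm_s": target_v,
                "true_movement_time_ms": target_mt,
                "true_movement_units": n_units,
                "dyn_speed_factor": d_v,
                "dyn_mt_factor": d_m,
                "baseline_peak_speed_mm_s": base_v,
                "baseline_movement_time_ms": base_mt,
            }
        )
    gt = pd.DataFrame(rows)
    return SubjectRecord(
        subject_id=subject_id,
        age_group=params.label,
        params=params,
        design=design,
        trials=trials,
        ground_truth=gt,
        seed_entropy=int(ss.entropy) if not isinstance(ss.entropy, (tuple, list)) else 0,
    )


def generate_cohort(
    seed: int,
    group_sizes: Optional[dict[str, int]] = None,
    age_params: Optional[dict[str, AgeGroupParams]] = None,
    design: Optional[BlockDesign] = None,
    fs: float = 100.0,
    noise_sd: Optional[float] = None,
) -> list[SubjectRecord]:
    """Generate a full cohort, one independent RNG stream per subject.

    Subject streams are spawned from the root seed by a fixed counter
    (``SeedSequence(seed, spawn_key=(i,))``), so each subject's data is
    independent of cohort composition and generation order.
    """
    if seed is None:
        raise ValueError("a seed is required")
    if group_sizes is None:
        group_sizes = {"1.5yo": 19, "3yo": 19, "adult": 20}
    if age_params is None:
        age_params = default_age_params()
    if design is None:
        design = BlockDesign()

    cohort = []
    counter = 0
    for label in AGE_GROUPS:
        if label not in group_sizes:
            continue
        for j in range(group_sizes[label]):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(counter,))
            cohort.append(
                generate_subject(
                    age_params[label],
                    design=design,
                    seed=ss,
                    fs=fs,
                    subject_id=f"{label}_{j + 1:02d}",
                    noise_sd=noise_sd,
                )
            )
            counter += 1
    return cohort


# ---------------------------------------------------------------------------
# gap injection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gap:
    """A contiguous run of missing samples on one or both markers."""

    marker: str  # "A", "B" or "both"
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.marker not in {"A", "B", "both"}:
            raise ValueError("marker must be 'A', 'B' or 'both'")
        if self.length < 1:
            raise ValueError("gap length must be >= 1")
        if self.start < 0:
            raise ValueError("gap start must be >= 0")


def inject_gaps(traj: MarkerTrajectory, gaps: Iterable[Gap]) -> MarkerTrajectory:
    """Mark sample ranges missing (NaN positions + mask), keeping the
    original values as hidden ground truth for recovery tests."""
    gaps = list(gaps)
    out = traj.copy()
    if not gaps:
        return out
    out.hidden_truth = {"A": traj.pos_a.copy(), "B": traj.pos_b.copy()}
    for gap in gaps:
        stop = gap.start + gap.length
        if stop > traj.n_samples:
            raise ValueError(
                f"gap [{gap.start}, {stop}) exceeds trial length {traj.n_samples}"
            )
        if gap.marker in {"A", "both"}:
            out.missing_a[gap.start:stop] = True
            out.pos_a[gap.start:stop] = np.nan
        if gap.marker in {"B", "both"}:
            out.missing_b[gap.start:stop] = True
            out.pos_b[gap.start:stop] = np.nan
    return out


# ---------------------------------------------------------------------------
# long-format export
# ---------------------------------------------------------------------------

def cohort_to_long_frame(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Long CSV schema: one row per sample, both markers wide."""
    frames = []
    for rec in cohort:
        for traj in rec.trials:
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": rec.subject_id,
                        "age_group": rec.age_group,
                        "trial": traj.trial,
                        "t_s": traj.t,
                        "mkrA_x_mm": traj.pos_a[:, 0],
                        "mkrA_y_mm": traj.pos_a[:, 1],
                        "mkrA_z_mm": traj.pos_a[:, 2],
                        "mkrB_x_mm": traj.pos_b[:, 0],
                        "mkrB_y_mm": traj.pos_b[:, 1],
                        "mkrB_z_mm": traj.pos_b[:, 2],
                        "missing_A": traj.missing_a.astype(int),
                        "missing_B": traj.missing_b.astype(int),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
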