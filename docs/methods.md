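# Methods

`adaptkin` re-implements a complete force-adaptation analysis of
drawer-opening kinematics in young children and adults: from raw
two-marker 100 Hz trajectories to trial-by-trial adaptation statistics,
together with a synthetic cohort generator that makes every stage
testable against known ground truth.

## The experimental design being modelled

Each subject performs 36 drawer pulls: warm-up (trials 1–2), baseline
(3–12) with normal drawer resistance, adaptation (13–24) with an
unannounced added weight (150 g for 1.5-year-olds, 250 g for
3-year-olds, 500 g for adults — scaled so the perturbation is felt
comparably), and deadaptation (25–36) with the weight removed. Three
dependent variables are computed per trial from drawer speed: peak
speed (mm/s), movement time (ms) and movement units (count of local
speed maxima; a proxy for corrective submovements). Force adaptation
appears as an initial error at trial 13, an exponential return toward
baseline, an opposite-signed aftereffect at trial 25, and washout.

## Synthetic cohorts (`synth`)

**Speed profiles.** A trial's speed is a superposition of minimum-jerk
submovements, v(t) = (D/T)·(30τ² − 60τ³ + 30τ⁴) with τ = t/T: the
standard bell-shaped profile of point-to-point movements. A main pull
carries the trial; children's multi-unit trials append 1–3 corrective
pulses (20% amplitude, 50% duration of the main pull), placed by
bisection so inter-pulse speed dips sit at max(45 mm/s, 18% of peak) —
far enough above the 30 mm/s offset threshold that a trial always forms
one onset–offset envelope, and deep enough (≥10 mm/s prominence after
filtering) to register as separate movement units. A fast trial cannot
physically carry several corrective pulses, so the drawn unit count is
capped at one unit per ~300 ms of movement time. The train is scaled
jointly in time and amplitude (a speed-preserving transformation) so
the analytic onset–offset movement time and the peak speed match their
per-trial targets exactly; both are stored as ground truth.

**Trial targets.** Each subject draws a baseline level (peak speed,
movement time) from the group distribution; each trial multiplies it by
a deterministic block dynamics factor and a mean-one log-normal
fluctuation. Speed dynamics: a 25% drop at trial 13 recovering as
1 − 0.25·exp(−k/τ) (reproducing the printed 354.57 → ≈266 mm/s group
drop), an 18.5% overshoot at trial 25 decaying the same way (printed
424.97 vs 358.57 mm/s). Movement time carries its own perturbation
fraction per age — 0.408 / 0.245 / 0.223 for 1.5yo / 3yo / adults —
because a fixed-displacement inverse coupling to speed provably cannot
reach the printed per-age adaptation slopes (the 1.5yo value exceeds
the coupling's attainable maximum). The fractions are solved in closed
form so the ordinary-least-squares slope of the noise-free
movement-time sequence over trials 13–24 equals the printed
−33.6 / −21.2 / −10.1 ms/trial given the time constants.

**Parameters that matter** (per age group, defaults in
`synth.default_age_params()`):

| parameter | 1.5yo | 3yo | adult | origin |
|---|---|---|---|---|
| baseline peak speed (mm/s) | 388.22 ± 112.2 | 303.10 ± 66.0 | 360.47 ± 50.8 | printed group means; SD = SE·√n |
| baseline movement time (ms) | 1052.34 ± 368.5 | 1152.61 ± 262.6 | 831.72 ± 112.2 | residual-block marginals (see below) |
| speed perturbation fraction | 0.25 | 0.25 | 0.25 | printed trial-13 drop |
| MT perturbation fraction | 0.408 | 0.245 | 0.223 | solved from printed slopes |
| adaptation τ (trials) | 4.0 | 2.5 | 1.0 | free parameter; chosen, see below |
| MT trial-to-trial CV | 0.375 | 0.302 | 0.113 | printed CVs minus trend contribution |
| speed trial-to-trial CV | 0.20 | 0.15 | 0.10 | chosen (not printed) |
| unit distribution over 1–4 | mean 1.54 | mean 1.46 | all 1 | printed baseline unit means |
| marker noise SD (mm) | 0.3 | 0.3 | 0.3 | chosen; sub-mm optical capture |

The movement-time baselines use the residual-error-analysis marginals
rather than the initial-error marginals: the latter average the
perturbed first adaptation trial into the "baseline" level. The chosen
values reproduce the printed overall baseline (~990 ms) and
first-adaptation (~1339 ms) cell means almost exactly.

The study does not report adaptation time constants; τ = 4.0/2.5/1.0
trials encodes its qualitative account (toddlers needed many trials,
adults were back near baseline by the second trial) and, for the
1.5-year-olds, sits near the τ that minimizes the perturbation
amplitude needed for the printed slope. The trial-level movement-time
CVs are derived so that the *measured* adaptation-block CV — which by
the study's definition includes the deterministic adaptation trend —
matches the printed 0.39/0.31/0.13.

**What the generator does not emulate.** Hand/arm kinematics, forces or
EMG; trial-length drift, fatigue or attention lapses; non-Gaussian
marker noise, marker swaps, or the occlusion statistics of a real
capture volume (gaps are injected explicitly via `inject_gaps`). A
green recovery test therefore establishes that the pipeline measures
what the generator encodes — not that the generator is the truth about
toddler motor control.

## Preprocessing (`preprocess`)

Single-marker gaps are reconstructed as other-marker position plus the
rigid offset, estimated as the coordinate-wise median over the 50
nearest both-present samples (the estimator is not specified by the
protocol; a median over a local window is robust to noise and
drift). Remaining both-marker gaps up to 500 samples are bridged by a
not-a-knot cubic spline (exact on cubic trajectories); longer gaps or
gaps touching the trial boundary invalidate the trial. Positions are
filtered with a 4th-order Butterworth low-pass at 8 Hz applied
forward–backward — the protocol names only "Butterworth, 8 Hz"; zero
phase is the kinematics convention, and acceptance tests pin the
resulting two-pass −6 dB point at the cutoff. Speed is the Euclidean
norm of the central-difference derivative of the front marker
(second-order accurate, no extra smoothing); displacement is the norm
of position minus the trial start. After filtering, 0.2 s is trimmed
from each trial end: zero-phase filtering leaves a noisy derivative
transient at the boundaries that would otherwise fool onset detection
on fast trials.

## Events and features (`events`)

Onset: first sample with speed > 30 mm/s. Offset: first sample after
onset with speed < 30 mm/s *and* displacement within 35 mm of the
maximum pullout (first-match; a candidate offset stands even if speed
re-exceeds the threshold later). Movement units: local maxima of the
filtered speed between onset and offset, plateaus collapsed, retained
at ≥10 mm/s prominence (the literal rule — every strict local maximum —
is `min_prominence=0`; the floor keeps residual sensor noise from
inflating the count and is consistent with counting on 8 Hz-filtered
speed). Detection failures set per-variable validity flags rather than
raising, so cohorts with unusable trials process end to end.

## Outlier exclusion (`outliers`)

Individual level: a non-exempt trial is excluded when it deviates more
than 2.5 leave-one-out SDs from the leave-one-out mean of the subject's
other valid non-warm-up trials ("the individual's remaining trials"
read literally; the all-in variant is a config switch). Trials 13 and
25 are exempt but still serve as reference data. Group level, applied
second: deviation beyond 2.5 SD of the group statistics, with trials 13
and 25 eligible. The group statistics are conditioned on trial position
within age group: pooling all trials would reject 2–5% of observations
— two orders of magnitude above the study's printed group-level rates
(0.02–0.03%) — and would systematically delete the expected elevation
of the early adaptation trials, biasing the trial-wise slopes toward
zero. The pooled literal reading remains available
(`options.group_per_trial=False`). Excluded trials become missing;
nothing is imputed.

## Metrics (`metrics`)

Per subject and variable: baseline mean (surviving trials 3–12);
initial error (trial 13 minus baseline); residual errors (mean of the
surviving subset of trials 22–24, respectively 34–36, minus baseline —
no backfilling); aftereffect (trial 25 minus baseline). The
movement-time CV is the sample SD over mean of the surviving
adaptation-block movement times (the block the study's variability
ANOVA addresses; an all-blocks switch exists). After exclusions the
measured CVs run some 10% below the generating values — the filters
clip the distribution tails — which affects levels, not the age
ordering.

## Statistics (`stats`)

The 3(age) × 2(condition) repeated-measures ANOVAs (initial error,
residual errors, aftereffect) use pingouin's mixed-design sums of
squares, with partial η² and pairwise between-group post-hocs
(independent t, Bonferroni, Cohen's d with pooled SD — the d formula is
not stated in the protocol) on the subject-level marginal means. Cells
with zero within-variance report F = 0, p = 1 rather than NaN.
Subjects missing a cell are dropped listwise, as the varying printed
denominators imply.

The trial-wise models are random-intercept LMMs,
`value ~ 1 + trial·age + (1 | subject)` per block, fitted by REML
(statsmodels MixedLM), with the trial covariate centered at the block
start and adults as the reference age (treatment coding; the study's
"customized contrasts" are unspecified). F tests use a Satterthwaite
denominator-df approximation computed from the closed-form REML
information matrix of (σ², τ²) — Kenward-Roger, which the study used,
is unavailable in this environment; the two coincide for balanced
random-intercept designs, and on simulated cohorts the within-subject
dfs land at ~600 for ~630 observations, the magnitude the study
prints. Multi-df tests combine one-df Satterthwaite values along the
eigenvectors of the contrast covariance. Degenerate fits (zero residual
variance, non-convergence) fall back to OLS — exact when the residual
variance vanishes — and are flagged `singular`. Per-age slopes are
linear combinations of the trial and interaction coefficients, with
SEs from the GLS covariance and pairwise contrasts. The one-way CV
ANOVA uses pingouin with the same post-hoc machinery.

## Numerical choices and degenerate inputs

Thresholds are strict inequalities exactly as stated (speed *exceeds*
30 → `>`; *fell below* → `<`). A zero reference SD excludes nothing.
Exclusion masks can only remove trials, never resurrect upstream
invalidations; the two filter levels run exactly once, in order. All
randomness flows from one root seed through counter-keyed
`SeedSequence` spawns (subject i's stream is independent of cohort
composition), and a missing seed is an error, not a silent default.
Sub-sample event timing is not interpolated: indices are reported at
the 10 ms grid, and the acceptance contract is one-sample agreement
with a 40× oversampled independently-filtered reference.

## Known limitations

The generator's trial fluctuations are independent across trials (no
slow drift or learning beyond the block dynamics), speed and
movement-time noise are independent given the dynamics, and the unit
count enters the trial geometry but not the movement-time target. The
prescribed outlier filters truncate the upper tail of the elevated
early-adaptation movement times, attenuating recovered 1.5yo slopes by
roughly 10% relative to the generating value — the study's own printed
slopes are post-filter estimates of its data, so this is a property of
the protocol, not a pipeline defect. Kenward-Roger dfs are
approximated by Satterthwaite. C3D ingestion is out of scope (CSV
only).
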