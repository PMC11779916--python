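# adaptkin

Trial-by-trial **force adaptation** analysis of drawer-opening
kinematics, for developmental motor-control research. When the
resistance of a familiar object changes unexpectedly, the first
movement misses (an *initial error*), subsequent movements recover
exponentially as the internal model updates, and removing the
perturbation produces an opposite-signed *aftereffect* that washes out.
`adaptkin` implements the full measurement chain for a 36-trial
drawer-pulling protocol (warm-up 1–2, baseline 3–12, adaptation 13–24
with added resistance, deadaptation 25–36) in three age groups
(1.5-year-olds, 3-year-olds, adults), plus a synthetic cohort generator
so every stage is testable without motion-capture data.

**Pipeline:** two-marker 100 Hz trajectories → pattern-fill /
spline-fill gap repair (≤500 samples) → zero-phase 4th-order
Butterworth low-pass at 8 Hz → drawer speed by central differences →
movement onset (speed > 30 mm/s) and offset (speed < 30 mm/s within
35 mm of max pullout) → per-trial **peak speed** v_max (mm/s),
**movement time** MT (ms) and **movement units** (local speed maxima) →
two-level ±2.5 SD outlier exclusion (individual leave-one-out, then
group) → per-subject adaptation contrasts and movement-time CV =
SD(MT)/mean(MT) → 3(age) × 2(condition) repeated-measures ANOVAs with
partial η² and Bonferroni post-hocs, and per-block random-intercept
mixed models

&nbsp;&nbsp;&nbsp;&nbsp;`value ~ 1 + trial · age + (1 | subject)`

with Satterthwaite-approximated F tests and per-age trial slopes.

The generator synthesizes each trial as a superposition of minimum-jerk
submovements, v(τ) = (D/T)(30τ² − 60τ³ + 30τ⁴), targeted at per-trial
feature triples drawn from age-specific block dynamics
(v_n = v_base·(1 − 0.25·e^{−(n−1)/τ}) during adaptation, with an
aftereffect overshoot during washout), log-normal trial-to-trial
variability, Gaussian marker noise, and injectable occlusion gaps with
hidden ground truth. Defaults are calibrated to the published group
means of the study design it emulates; see `docs/methods.md`.

## Worked example

```bash
adaptkin analyze --seed 42 --out runs/demo
adaptkin report --run-dir runs/demo
```

runs the whole chain on a simulated 19/19/20-subject cohort and prints,
among other lines:

```
ANOVA peak_speed_mm_s/initial    initial        F(1, 54) = 196.96, p = 0.0000, eta_p^2 = 0.785
ANOVA movement_time_ms/initial   initial        F(1, 54) = 41.91,  p = 0.0000, eta_p^2 = 0.437
ANOVA movement_units/initial     initial        F(1, 54) = 188.89, p = 0.0000, eta_p^2 = 0.778
CV ANOVA (movement time)         age F(2, 55) = 91.51, p = 0.0000
LMM   movement_time_ms/adaptation  slopes/trial  1.5yo: -33.77, 3yo: -24.32, adult: -8.98
```

Reading: the resistance step perturbed all three variables (significant
initial-error main effects — peak speed dropped ~25% at trial 13);
trial-to-trial movement-time variability differs strongly by age; and
the recovered adaptation slopes (−33.8 / −24.3 / −9.0 ms per trial)
reproduce the generating per-age values (−33.6 / −21.2 / −10.1):
toddlers start slower and adapt in larger steps, adults are back near
baseline within a trial or two. Artifacts (`features.csv`,
`exclusions.csv`, `summary.csv`, `stats.json`, `ground_truth.csv`, and
a `manifest.json` with the config hash and seed) land in `runs/demo`;
identical config + seed reproduces them byte for byte.

The library surface mirrors the pipeline: `generate_cohort`,
`inject_gaps`, `preprocess_trial`, `extract_features`,
`apply_outlier_filters`, `summarize_cohort`, `rm_anova_3x2`,
`fit_trialwise_lmm`, `anova_cv_by_age`, `run_pipeline`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the pipeline end to end (simulation → preprocessing → features
→ exclusion → metrics → full statistics) on a seeded demo cohort,
writes the run artifacts next to the output file, and writes the
results-summary JSON to `--out`.
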