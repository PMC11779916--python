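"""Generator correctness: minimum-jerk identities, trial construction,
subject dynamics and gap injection."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import adaptkin as ak
from adaptkin.synth import (
    Gap,
    SubmovementSpec,
    _analytic_movement_time,
    pulse_train_speed,
)


def brute_local_maxima(y):
    """Independent neighbor-scan count of strict local maxima (no
    prominence rule), plateaus collapsed."""
    count = 0
    i = 1
    n = len(y)
    while i < n - 1:
        j = i
        while j < n - 1 and y[j + 1] == y[j]:
            j += 1
        if y[i - 1] < y[i] and j < n - 1 and y[j + 1] < y[j]:
            count += 1
        i = j + 1
    return count


class TestMinJerk:
    def test_boundary_zero(self):
        assert ak.min_jerk_speed(100, 1, 0.0) == 0.0
        assert ak.min_jerk_speed(100, 1, 1.0) == 0.0
        assert ak.min_jerk_speed(100, 1, -0.3) == 0.0
        assert ak.min_jerk_speed(100, 1, 1.7) == 0.0

    def test_peak_value(self):
        # 30/16 - 60/8 + 30/4 = 1.875 at the midpoint
        assert ak.min_jerk_speed(100, 1, 0.5) == pytest.approx(187.5, abs=1e-12)

    @pytest.mark.parametrize("D,T", [(250, 0.8), (100, 1.0), (400, 2.3)])
    def test_integral_equals_amplitude(self, D, T):
        area, _ = quad(lambda t: ak.min_jerk_speed(D, T, t), 0, T, limit=200)
        assert area == pytest.approx(D, rel=1e-6)

    def test_displacement_closed_form(self):
        t = np.linspace(0, 1.5, 301)
        num = np.array([quad(lambda u: ak.min_jerk_speed(300, 1.5, u), 0, ti)[0] for ti in t[::50]])
        assert ak.min_jerk_displacement(300, 1.5, t[::50]) == pytest.approx(num, abs=1e-6)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            ak.min_jerk_speed(100, 0, 0.5)
        with pytest.raises(ValueError):
            ak.min_jerk_displacement(100, -1, 0.5)


class TestGenerateTrial:
    def test_final_displacement_is_sum_of_amplitudes(self):
        traj = ak.generate_trial([SubmovementSpec(300, 1.0, 0.0)], fs=100)
        disp = np.linalg.norm(traj.pos_a[-1] - traj.pos_a[0])
        assert disp == pytest.approx(300.0, abs=1e-9)

    def test_two_separated_pulses_two_maxima(self):
        specs = [SubmovementSpec(200, 0.8, 0.0), SubmovementSpec(150, 0.8, 1.2)]
        t = np.linspace(-0.1, 2.2, 5000)
        v = pulse_train_speed(specs, t)
        assert brute_local_maxima(v) == 2

    def test_length_covers_duration(self):
        traj = ak.generate_trial([SubmovementSpec(300, 1.0, 0.0)], fs=100, lead_in_s=0, lead_out_s=0)
        assert traj.n_samples >= 100

    def test_marker_rigidity_and_noise(self, rng):
        specs = [SubmovementSpec(300, 1.0, 0.0)]
        clean = ak.generate_trial(specs, fs=100)
        offsets = clean.pos_b - clean.pos_a
        assert np.allclose(offsets, offsets[0])
        noisy = ak.generate_trial(specs, fs=100, noise_sd=0.5, rng=rng)
        assert not np.allclose(noisy.pos_a, clean.pos_a)

    def test_parameter_validation(self, rng):
        with pytest.raises(ValueError):
            ak.generate_trial([], fs=100)
        with pytest.raises(ValueError):
            ak.generate_trial([SubmovementSpec(300, 1.0, 0.0)], fs=0)
        with pytest.raises(ValueError):  # noise without rng is silent nondeterminism
            ak.generate_trial([SubmovementSpec(300, 1.0, 0.0)], fs=100, noise_sd=0.5)


class TestBuildTrial:
    @pytest.mark.parametrize("peak,mt,units", [(354.57, 990.0, 1), (266.0, 1340.0, 2), (420.0, 800.0, 3)])
    def test_targets_hit_exactly(self, peak, mt, units):
        specs = ak.build_trial_submovements(peak, mt, units)
        assert max(sp.peak_speed for sp in specs) == pytest.approx(peak, rel=1e-9)
        _, _, mt_s = _analytic_movement_time(specs)
        assert mt_s * 1000 == pytest.approx(mt, rel=2e-3)
        t = np.linspace(0, max(sp.end_s for sp in specs), 8000)
        assert brute_local_maxima(pulse_train_speed(specs, t)) == units

    def test_dip_stays_above_offset_threshold(self):
        from scipy.signal import argrelmax

        specs = ak.build_trial_submovements(300.0, 1200.0, 3)
        t = np.linspace(0, max(sp.end_s for sp in specs), 8000)
        v = pulse_train_speed(specs, t)
        peaks = argrelmax(v)[0]
        assert len(peaks) == 3
        assert v[peaks[0] : peaks[-1]].min() > 40.0


class TestGenerateSubject:
    def test_seed_required(self, age_params):
        with pytest.raises(ValueError, match="seed"):
            ak.generate_subject(age_params["adult"], seed=None)

    def test_printed_trial13_drop(self, age_params):
        """25% perturbation on a 354.57 mm/s baseline targets 265.93 mm/s
        at the first adaptation trial."""
        import dataclasses

        params = dataclasses.replace(
            age_params["adult"],
            baseline_peak_speed_mean=354.57, baseline_peak_speed_sd=0.0,
            perturbation_fraction=0.25, speed_trial_cv=0.0, mt_trial_cv=0.0,
        )
        rec = ak.generate_subject(params, seed=3, subject_id="s", noise_sd=0.0)
        gt = rec.ground_truth.set_index("trial")
        assert gt.loc[13, "true_peak_speed_mm_s"] == pytest.approx(265.9275, abs=1e-6)

    def test_zero_perturbation_degenerate(self, age_params):
        import dataclasses

        params = dataclasses.replace(
            age_params["adult"], perturbation_fraction=0.0, mt_perturbation_fraction=0.0,
            aftereffect_fraction=0.0, mt_aftereffect_fraction=0.0,
            speed_trial_cv=0.0, mt_trial_cv=0.0,
        )
        rec = ak.generate_subject(params, seed=3, subject_id="s", noise_sd=0.0)
        gt = rec.ground_truth
        assert np.allclose(gt["true_peak_speed_mm_s"], gt["true_peak_speed_mm_s"].iloc[0])

    def test_tiny_tau_recovers_by_second_trial(self, age_params):
        import dataclasses

        params = dataclasses.replace(
            age_params["adult"], adapt_tau=1e-9, speed_trial_cv=0.0, mt_trial_cv=0.0,
        )
        rec = ak.generate_subject(params, seed=3, subject_id="s", noise_sd=0.0)
        gt = rec.ground_truth.set_index("trial")
        base = gt.loc[5, "true_peak_speed_mm_s"]
        assert gt.loc[14, "true_peak_speed_mm_s"] == pytest.approx(base, rel=1e-9)

    def test_adaptation_monotone_toward_baseline(self, age_params, design):
        rec = ak.generate_subject(age_params["1.5yo"], seed=9, subject_id="s", noise_sd=0.0)
        gt = rec.ground_truth.set_index("trial")
        dv = gt.loc[list(design.adaptation), "dyn_speed_factor"].to_numpy()
        dm = gt.loc[list(design.adaptation), "dyn_mt_factor"].to_numpy()
        assert np.all(np.diff(dv) > 0) and dv[-1] <= 1.0
        assert np.all(np.diff(dm) < 0) and dm[-1] >= 1.0

    def test_same_seed_bit_identical(self, age_params):
        a = ak.generate_subject(age_params["3yo"], seed=5, subject_id="x")
        b = ak.generate_subject(age_params["3yo"], seed=5, subject_id="x")
        assert a.ground_truth.equals(b.ground_truth)
        for ta, tb in zip(a.trials, b.trials):
            np.testing.assert_array_equal(ta.pos_a, tb.pos_a)
            np.testing.assert_array_equal(ta.pos_b, tb.pos_b)

    def test_cohort_subject_streams_order_independent(self, age_params):
        full = ak.generate_cohort(seed=21, group_sizes={"1.5yo": 2, "3yo": 1, "adult": 1})
        again = ak.generate_cohort(seed=21, group_sizes={"1.5yo": 2, "3yo": 1, "adult": 1})
        for a, b in zip(full, again):
            np.testing.assert_array_equal(a.trials[0].pos_a, b.trials[0].pos_a)


class TestInjectGaps:
    def test_gap_on_a_leaves_b_untouched(self, noisefree_subject):
        traj = noisefree_subject.trials[0]
        out = ak.inject_gaps(traj, [Gap("A", 10, 50)])
        np.testing.assert_array_equal(out.pos_b, traj.pos_b)
        assert out.missing_a[10:60].all() and np.isnan(out.pos_a[10:60]).all()
        assert not out.missing_b.any()

    def test_zero_gaps_identity(self, noisefree_subject):
        traj = noisefree_subject.trials[0]
        out = ak.inject_gaps(traj, [])
        np.testing.assert_array_equal(out.pos_a, traj.pos_a)
        assert out.hidden_truth is None

    def test_gap_exceeding_length_raises(self, noisefree_subject):
        traj = noisefree_subject.trials[0]
        with pytest.raises(ValueError, match="exceeds trial length"):
            ak.inject_gaps(traj, [Gap("both", traj.n_samples - 10, 20)])

    def test_hidden_truth_retained(self, noisefree_subject):
        traj = noisefree_subject.trials[0]
        out = ak.inject_gaps(traj, [Gap("A", 10, 30)])
        np.testing.assert_array_equal(out.hidden_truth["A"], traj.pos_a)
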