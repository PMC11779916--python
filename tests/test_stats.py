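"""Inferential layer: ANOVA identities, LMM behavior, df approximations."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import adaptkin as ak
from adaptkin.config import AnalysisOptions


def summary_frame(rows):
    """Rows: (subject, age, baseline, cell2) -> summary-table format."""
    out = []
    for sid, age, base, cell in rows:
        out.append(
            {
                "subject_id": sid, "age_group": age, "variable": "movement_time_ms",
                "baseline_mean": base, "first_adaptation_value": cell,
                "last3_adaptation_mean": np.nan, "first_deadaptation_value": np.nan,
                "last3_deadaptation_mean": np.nan, "movement_time_cv": np.nan,
            }
        )
    return pd.DataFrame(out)


class TestRmAnova:
    def test_single_group_within_f_equals_paired_t_squared(self, rng):
        base = 1000 + 50 * rng.standard_normal(14)
        cell = base + 120 + 40 * rng.standard_normal(14)
        rows = [(f"s{i}", "adult", base[i], cell[i]) for i in range(14)]
        res = ak.rm_anova_3x2(summary_frame(rows), "movement_time_ms", "initial")
        t, _ = sps.ttest_rel(cell, base)
        F = res.table.loc[res.table.effect == "initial", "F"].iloc[0]
        assert F == pytest.approx(t**2, rel=1e-8)

    def test_identical_cells_f_zero_p_one(self):
        rows = [(f"s{i}", "adult", 1000.0 + i, 1000.0 + i) for i in range(8)]
        res = ak.rm_anova_3x2(summary_frame(rows), "movement_time_ms", "initial")
        row = res.table[res.table.effect == "initial"].iloc[0]
        assert row.F == 0.0 and row.p == 1.0

    def test_three_group_structure(self, rng):
        rows = []
        for g, n, shift in (("1.5yo", 7, 200), ("3yo", 7, 150), ("adult", 8, 100)):
            for i in range(n):
                b = 1000 + 80 * rng.standard_normal()
                rows.append((f"{g}{i}", g, b, b + shift + 50 * rng.standard_normal()))
        res = ak.rm_anova_3x2(summary_frame(rows), "movement_time_ms", "initial")
        assert set(res.table.effect) == {"age", "initial", "age x initial"}
        assert ((res.table.partial_eta_sq >= 0) & (res.table.partial_eta_sq <= 1)).all()
        assert (res.posthoc.p_bonf >= res.posthoc.p - 1e-15).all()
        assert len(res.posthoc) == 3

    def test_missing_cell_listwise_drop(self, rng):
        rows = [(f"s{i}", "adult", 1000.0, 1100.0 + 10 * rng.standard_normal()) for i in range(6)]
        df = summary_frame(rows)
        df.loc[0, "first_adaptation_value"] = np.nan
        res = ak.rm_anova_3x2(df, "movement_time_ms", "initial")
        assert res.n_subjects == 5

    def test_insufficient_cell_named(self):
        rows = [("s1", "adult", 1000.0, 1100.0), ("s2", "3yo", 900.0, 950.0), ("s3", "3yo", 910.0, 955.0)]
        with pytest.raises(ValueError, match="adult"):
            ak.rm_anova_3x2(summary_frame(rows), "movement_time_ms", "initial")


class TestCvAnova:
    def _cv_summary(self, groups):
        rows = []
        for g, values in groups.items():
            for i, v in enumerate(values):
                rows.append(
                    {
                        "subject_id": f"{g}{i}", "age_group": g, "variable": "movement_time_ms",
                        "baseline_mean": 1000.0, "first_adaptation_value": 1100.0,
                        "last3_adaptation_mean": np.nan, "first_deadaptation_value": np.nan,
                        "last3_deadaptation_mean": np.nan, "movement_time_cv": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_two_groups_f_equals_t_squared(self, rng):
        a = 0.39 + 0.05 * rng.standard_normal(10)
        b = 0.13 + 0.02 * rng.standard_normal(12)
        res = ak.anova_cv_by_age(self._cv_summary({"1.5yo": a, "adult": b}))
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert res.table.F.iloc[0] == pytest.approx(t**2, rel=1e-8)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ak.anova_cv_by_age(self._cv_summary({"adult": [0.1, 0.12, 0.13]}))

    def test_equal_means_small_f(self, rng):
        groups = {g: 0.25 + 0.03 * rng.standard_normal(200) for g in ("1.5yo", "3yo", "adult")}
        res = ak.anova_cv_by_age(self._cv_summary(groups))
        assert res.table.F.iloc[0] < 4.0


def lmm_frame(rng, slopes={"1.5yo": -33.6, "3yo": -21.2, "adult": -10.1},
              intercepts={"1.5yo": 1750.0, "3yo": 1520.0, "adult": 1130.0},
              n_per_group=6, noise=120.0, subject_sd=150.0, block=(13, 24)):
    rows = []
    for g, slope in slopes.items():
        for i in range(n_per_group):
            u = subject_sd * rng.standard_normal()
            for trial in range(block[0], block[1] + 1):
                k = trial - block[0]
                y = intercepts[g] + u + slope * k + noise * rng.standard_normal()
                rows.append(
                    {"subject_id": f"{g}{i}", "age_group": g, "trial": trial,
                     "block": "adaptation", "movement_time_ms": y, "movement_time_ms__ok": True}
                )
    return pd.DataFrame(rows)


class TestTrialwiseLmm:
    def test_zero_variance_reduces_to_ols(self):
        """No noise, no random intercepts: the estimated common slope is
        the generating one to numerical precision."""
        rows = []
        for i in range(5):
            for trial in range(13, 25):
                rows.append(
                    {"subject_id": f"s{i}", "age_group": "adult", "trial": trial,
                     "block": "adaptation",
                     "movement_time_ms": 1200.0 - 10.0 * (trial - 13),
                     "movement_time_ms__ok": True}
                )
        res = ak.fit_trialwise_lmm(pd.DataFrame(rows), "movement_time_ms", "adaptation")
        slope = res.slopes.slope.iloc[0]
        assert slope == pytest.approx(-10.0, abs=1e-6)
        assert res.singular

    def test_slope_recovery_with_noise(self, rng):
        df = lmm_frame(rng, n_per_group=10, noise=60.0)
        res = ak.fit_trialwise_lmm(df, "movement_time_ms", "adaptation")
        got = res.slopes.set_index("age_group").slope
        for g, s in (("1.5yo", -33.6), ("3yo", -21.2), ("adult", -10.1)):
            assert got[g] == pytest.approx(s, abs=3 * res.slopes.set_index("age_group").se[g])

    def test_matches_lme4_reml(self, rng, tmp_path):
        """Cross-check against R lme4 (REML) on the same data: fixed
        effects and variance components agree."""
        df = lmm_frame(rng, n_per_group=5, noise=100.0)
        res = ak.fit_trialwise_lmm(df, "movement_time_ms", "adaptation")
        csv = tmp_path / "lmm.csv"
        d = df.copy()
        d["trial_c"] = d.trial - 13
        d.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            """
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
            d$age_group <- relevel(factor(d$age_group), ref="adult")
            m <- lmer(movement_time_ms ~ 1 + trial_c * age_group + (1|subject_id), data=d, REML=TRUE)
            fe <- fixef(m)
            vc <- as.data.frame(VarCorr(m))
            cat(paste(c(fe, vc$vcov), collapse=","))
            """
        )
        out = subprocess.run(
            ["Rscript", str(rscript), str(csv)], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        vals = np.array([float(x) for x in out.stdout.strip().split(",")])
        r_fe, r_tau2, r_sigma2 = vals[:6], vals[6], vals[7]
        my = res.coefficients.set_index("name").estimate
        mine = np.array(
            [my["Intercept"], my["trial"], my["age[1.5yo]"], my["age[3yo]"],
             my["trial:age[1.5yo]"], my["trial:age[3yo]"]]
        )
        np.testing.assert_allclose(mine, r_fe, rtol=1e-3)
        assert res.tau2 == pytest.approx(r_tau2, rel=5e-2)
        assert res.sigma2 == pytest.approx(r_sigma2, rel=1e-2)

    def test_satterthwaite_dfs_plausible(self, rng):
        df = lmm_frame(rng, n_per_group=8, noise=80.0)
        res = ak.fit_trialwise_lmm(df, "movement_time_ms", "adaptation")
        n_obs, n_subj = res.n_obs, res.n_subjects
        tab = res.fixed_table.set_index("term")
        # within-subject covariate dfs close to the residual count,
        # between-subject df of the same order as the subject count
        assert n_obs - n_subj - 10 < tab.loc["trial", "df2"] <= n_obs
        assert 2 < tab.loc["age", "df2"] < n_obs
        assert (res.slopes.df > 2).all()

    def test_permuted_ages_interaction_null(self, rng):
        """With shuffled age labels the trial x age interaction should
        rarely reach significance."""
        df = lmm_frame(rng, n_per_group=6, noise=100.0)
        opts = AnalysisOptions(lmm_df_method="residual")
        hits = 0
        n_perm = 20
        ages = df.groupby("subject_id").age_group.first()
        for _ in range(n_perm):
            perm = pd.Series(rng.permutation(ages.values), index=ages.index)
            shuffled = df.copy()
            shuffled["age_group"] = shuffled.subject_id.map(perm)
            res = ak.fit_trialwise_lmm(shuffled, "movement_time_ms", "adaptation", options=opts)
            p = res.fixed_table.set_index("term").loc["trial:age", "p"]
            hits += p < 0.05
        assert hits <= 3

    def test_block_restriction(self, rng):
        df = lmm_frame(rng)
        with pytest.raises(ValueError):
            ak.fit_trialwise_lmm(df, "movement_time_ms", "baseline")
        with pytest.raises(ValueError):
            ak.fit_trialwise_lmm(df, "movement_time_ms", "deadaptation")  # no such trials


class TestEffectSizes:
    def test_cohen_d_pooled(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([3.0, 4.0, 5.0, 6.0])
        sp = np.sqrt(((3 * x.var(ddof=1)) + (3 * y.var(ddof=1))) / 6)
        assert ak.cohen_d(x, y) == pytest.approx((x.mean() - y.mean()) / sp)

    def test_pairwise_bonferroni_floor(self, rng):
        df = pd.DataFrame(
            {
                "age_group": ["1.5yo"] * 8 + ["3yo"] * 8 + ["adult"] * 8,
                "value": np.concatenate(
                    [rng.normal(0.39, 0.05, 8), rng.normal(0.31, 0.05, 8), rng.normal(0.13, 0.02, 8)]
                ),
            }
        )
        ph = ak.pairwise_between(df, "value")
        assert (ph.p_bonf <= 1.0).all()
        assert (ph.p_bonf >= ph.p - 1e-15).all()
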