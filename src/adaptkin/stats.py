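"""Inferential layer: mixed-design ANOVAs and trial-wise mixed models.

Three families of tests, mirroring the analysis protocol:

* 3 (age) x 2 (baseline vs. contrast cell) mixed-design repeated
  measures ANOVAs for initial error, residual errors and aftereffect,
  with partial eta squared and Bonferroni-corrected between-group
  post-hocs (Cohen's d, pooled SD);
* random-intercept linear mixed models per block,
  ``value ~ 1 + trial * age + (1 | subject)``, with per-age trial
  slopes and slope contrasts; F tests use a Satterthwaite
  denominator-df approximation (the Kenward-Roger correction it stands
  in for coincides with it for balanced random-intercept designs);
* a one-way ANOVA on the per-subject movement-time CV across ages.

The ANOVA sums of squares come from pingouin; the mixed models from
statsmodels MixedLM (REML). Degenerate fits (zero residual variance)
fall back to OLS, which is the exact estimate in that case.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps

from .config import AnalysisOptions
from .containers import AGE_GROUPS, BlockDesign

__all__ = [
    "AnovaResult",
    "LmmResult",
    "rm_anova_3x2",
    "anova_cv_by_age",
    "fit_trialwise_lmm",
    "pairwise_between",
    "cohen_d",
]

logger = logging.getLogger(__name__)

#: Contrast name -> summary-table column of the second within cell.
CONTRAST_CELLS = {
    "initial": "first_adaptation_value",
    "residual_adapt": "last3_adaptation_mean",
    "aftereffect": "first_deadaptation_value",
    "residual_deadapt": "last3_deadaptation_mean",
}


@dataclass
class AnovaResult:
    """ANOVA table plus Bonferroni-corrected pairwise post-hocs."""

    table: pd.DataFrame  # effect, F, df1, df2, p, partial_eta_sq
    posthoc: pd.DataFrame
    n_subjects: int
    contrast: str = ""
    variable: str = ""


@dataclass
class LmmResult:
    """Random-intercept LMM fixed-effect tests and per-age trial slopes."""

    fixed_table: pd.DataFrame  # term, F, df1, df2, p, partial_eta_sq
    coefficients: pd.DataFrame  # name, estimate, se
    slopes: pd.DataFrame  # age_group, slope, se, df, p
    slope_contrasts: pd.DataFrame
    sigma2: float
    tau2: float
    n_obs: int
    n_subjects: int
    converged: bool = True
    singular: bool = False
    df_method: str = "satterthwaite"
    variable: str = ""
    block: str = ""


def cohen_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled SD."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0 if x.mean() == y.mean() else np.inf * np.sign(x.mean() - y.mean())
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def pairwise_between(df: pd.DataFrame, value_col: str, group_col: str = "age_group") -> pd.DataFrame:
    """Pairwise independent-sample comparisons with Bonferroni correction."""
    groups = [g for g in AGE_GROUPS if g in set(df[group_col])]
    groups += [g for g in sorted(set(df[group_col])) if g not in groups]
    pairs = list(combinations(groups, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        xa = df.loc[df[group_col] == a, value_col].dropna().to_numpy()
        xb = df.loc[df[group_col] == b, value_col].dropna().to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-constant cells (e.g. adult unit counts)
            t, p = sps.ttest_ind(xa, xb, equal_var=True)
        rows.append(
            {
                "A": a, "B": b, "mean_A": xa.mean(), "mean_B": xb.mean(),
                "t": float(t), "p": float(p), "p_bonf": min(1.0, float(p) * m),
                "cohen_d": cohen_d(xa, xb), "n_A": len(xa), "n_B": len(xb),
            }
        )
    return pd.DataFrame(rows)


def _fix_degenerate(table: pd.DataFrame) -> pd.DataFrame:
    """Zero effect SS with zero error SS is 'no effect', not NaN."""
    out = table.copy()
    bad = ~np.isfinite(out["F"])
    if "SS" in out.columns:
        zero_eff = out["SS"].abs() < 1e-12
        out.loc[bad & zero_eff, "F"] = 0.0
        out.loc[bad & zero_eff, "p"] = 1.0
        out.loc[bad & zero_eff, "partial_eta_sq"] = 0.0
    return out


def rm_anova_3x2(summary: pd.DataFrame, variable: str, contrast: str) -> AnovaResult:
    """Mixed-design ANOVA: within factor baseline vs. one contrast cell,
    between factor age. Subjects missing either cell are dropped
    listwise; the post-hocs compare age groups on the subject-level
    marginal means (mean of the two cells).
    """
    if contrast not in CONTRAST_CELLS:
        raise ValueError(f"unknown contrast {contrast!r}; one of {sorted(CONTRAST_CELLS)}")
    cell2 = CONTRAST_CELLS[contrast]
    sub = summary[summary["variable"] == variable]
    wide = sub[["subject_id", "age_group", "baseline_mean", cell2]].dropna()
    counts = wide.groupby("age_group")["subject_id"].count()
    thin = counts[counts < 2]
    if len(thin) or wide.empty:
        cells = ", ".join(f"{g} (n={n})" for g, n in thin.items()) or "all age groups"
        raise ValueError(f"insufficient data for {variable}/{contrast}: {cells}")

    long = wide.melt(
        id_vars=["subject_id", "age_group"],
        value_vars=["baseline_mean", cell2],
        var_name="condition", value_name="value",
    )
    n_groups = wide["age_group"].nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n_groups > 1:
            aov = pg.mixed_anova(
                data=long, dv="value", within="condition", subject="subject_id", between="age_group"
            )
            name_map = {"age_group": "age", "condition": contrast, "Interaction": f"age x {contrast}"}
            table = pd.DataFrame(
                {
                    "effect": [name_map.get(s, s) for s in aov["Source"]],
                    "F": aov["F"].to_numpy(dtype=float),
                    "df1": aov["DF1"].to_numpy(dtype=float),
                    "df2": aov["DF2"].to_numpy(dtype=float),
                    "p": aov["p_unc"].to_numpy(dtype=float),
                    "partial_eta_sq": aov["np2"].to_numpy(dtype=float),
                    "SS": aov["SS"].to_numpy(dtype=float),
                }
            )
        else:
            aov = pg.rm_anova(
                data=long, dv="value", within="condition", subject="subject_id", detailed=True
            )
            eff = aov[aov["Source"] == "condition"].iloc[0]
            err = aov[aov["Source"] == "Error"].iloc[0]
            ss_eff, ss_err = float(eff["SS"]), float(err["SS"])
            # pingouin omits F/p entirely when the within variance is 0
            f_val = float(eff["F"]) if "F" in aov.columns else np.nan
            p_val = float(eff["p_unc"]) if "p_unc" in aov.columns else np.nan
            table = pd.DataFrame(
                [{
                    "effect": contrast, "F": f_val,
                    "df1": float(eff["DF"]), "df2": float(err["DF"]),
                    "p": p_val,
                    "partial_eta_sq": ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0,
                    "SS": ss_eff,
                }]
            )
    table = _fix_degenerate(table)
    wide = wide.assign(marginal=0.5 * (wide["baseline_mean"] + wide[cell2]))
    posthoc = pairwise_between(wide, "marginal") if n_groups > 1 else pd.DataFrame()
    return AnovaResult(
        table=table, posthoc=posthoc, n_subjects=len(wide), contrast=contrast, variable=variable
    )


def anova_cv_by_age(summary: pd.DataFrame) -> AnovaResult:
    """One-way between-subjects ANOVA on the movement-time CV."""
    cv = summary[(summary["variable"] == "movement_time_ms")][
        ["subject_id", "age_group", "movement_time_cv"]
    ].dropna()
    if cv["age_group"].nunique() < 2:
        raise ValueError("CV ANOVA requires at least two age groups")
    aov = pg.anova(data=cv, dv="movement_time_cv", between="age_group", detailed=True)
    eff = aov[aov["Source"] == "age_group"].iloc[0]
    resid = aov[aov["Source"] == "Within"].iloc[0]
    table = pd.DataFrame(
        [{
            "effect": "age", "F": float(eff["F"]), "df1": float(eff["DF"]),
            "df2": float(resid["DF"]), "p": float(eff["p_unc"]),
            "partial_eta_sq": float(eff["np2"]), "SS": float(eff["SS"]),
        }]
    )
    table = _fix_degenerate(table)
    posthoc = pairwise_between(cv, "movement_time_cv")
    return AnovaResult(table=table, posthoc=posthoc, n_subjects=len(cv), contrast="cv", variable="movement_time_cv")


# ---------------------------------------------------------------------------
# trial-wise linear mixed model
# ---------------------------------------------------------------------------

def _lmm_design(df: pd.DataFrame, block_start: int) -> tuple[np.ndarray, list[str], dict[str, list[int]], list[str]]:
    """Treatment-coded design matrix with adults as reference.

    Columns: intercept, centered trial, age dummies, trial x age. The
    trial covariate is centered at the first block trial so the
    intercept is the initial level.
    """
    ages = [g for g in AGE_GROUPS if g in set(df["age_group"])]
    non_ref = [g for g in ages if g != "adult"] if "adult" in ages else ages[1:]
    trial_c = df["trial"].to_numpy(dtype=float) - block_start
    cols = [np.ones(len(df)), trial_c]
    names = ["Intercept", "trial"]
    terms: dict[str, list[int]] = {"trial": [1], "age": [], "trial:age": []}
    for g in non_ref:
        d = (df["age_group"] == g).to_numpy(dtype=float)
        cols.append(d)
        terms["age"].append(len(names))
        names.append(f"age[{g}]")
    for g in non_ref:
        d = (df["age_group"] == g).to_numpy(dtype=float)
        cols.append(d * trial_c)
        terms["trial:age"].append(len(names))
        names.append(f"trial:age[{g}]")
    return np.column_stack(cols), names, terms, ages


class _SatterthwaiteEngine:
    """Satterthwaite denominator dfs for a fitted random-intercept model.

    For V = sigma^2 I + tau^2 Z Z', the df of a 1-df contrast L is
    2 theta^2 / Var(theta) with theta = Var(L beta-hat); Var(theta) is a
    delta-method variance through the REML information matrix of
    (sigma^2, tau^2). Multi-df F tests combine 1-df contrasts along the
    eigenvectors of the contrast covariance (the lmerTest recipe).
    Dense O(N^2) memory; intended for N up to a few thousand.
    """

    def __init__(self, X: np.ndarray, group_idx: list[np.ndarray], sigma2: float, tau2: float):
        n = X.shape[0]
        vinv = np.zeros((n, n))
        zzt = np.zeros((n, n))
        for idx in group_idx:
            k = len(idx)
            block = -(tau2 / (sigma2 + k * tau2)) * np.ones((k, k)) / sigma2
            block[np.diag_indices(k)] += 1.0 / sigma2
            vinv[np.ix_(idx, idx)] = block
            zzt[np.ix_(idx, idx)] = 1.0
        self.X = X
        self.vinv = vinv
        self.C = np.linalg.inv(X.T @ vinv @ X)
        vinv_x = vinv @ X
        P = vinv - vinv_x @ self.C @ vinv_x.T
        A = [np.eye(n), zzt]  # d V / d sigma2, d V / d tau2
        K = np.empty((2, 2))
        PA = [P @ a for a in A]
        for i in range(2):
            for j in range(2):
                K[i, j] = 0.5 * np.trace(PA[i] @ PA[j])
        # Covariance of the variance-component estimates; pseudo-inverse
        # guards boundary fits (tau2 = 0) where K is singular.
        self.theta_cov = np.linalg.pinv(K)
        self._vinv_x = vinv_x
        self._A = A

    def df_1d(self, l: np.ndarray) -> float:
        theta = float(l @ self.C @ l)
        b = self.C @ l
        w = self._vinv_x @ b
        grad = np.array([float(w @ a @ w) for a in self._A])
        var_theta = float(grad @ self.theta_cov @ grad)
        if var_theta <= 0:
            return np.inf
        return 2.0 * theta**2 / var_theta

    def df_multi(self, L: np.ndarray) -> float:
        lam = L @ self.C @ L.T
        q = L.shape[0]
        if q == 1:
            return self.df_1d(L[0])
        vals, vecs = np.linalg.eigh(lam)
        nus = []
        for i in range(q):
            l = vecs[:, i] @ L
            nus.append(self.df_1d(l))
        e_sum = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0 and np.isfinite(nu))
        if e_sum <= q:
            return np.inf
        return 2.0 * e_sum / (e_sum - q)


def fit_trialwise_lmm(
    df: pd.DataFrame,
    variable: str,
    block: str = "adaptation",
    design: Optional[BlockDesign] = None,
    options: Optional[AnalysisOptions] = None,
) -> LmmResult:
    """Fit ``variable ~ 1 + trial * age + (1 | subject)`` on one block.

    Only surviving trials of the chosen block enter (``__ok`` mask when
    present, otherwise validity flags). Reports Type-III-style Wald F
    tests for trial, age and their interaction, per-age trial slopes
    with standard errors, and pairwise slope contrasts.
    """
    design = design or BlockDesign()
    opts = options or AnalysisOptions()
    if block not in {"adaptation", "deadaptation"}:
        raise ValueError("block must be 'adaptation' or 'deadaptation'")
    trials = getattr(design, block)
    ok_col = f"{variable}__ok"
    keep = df["trial"].isin(trials)
    keep &= df[ok_col] if ok_col in df.columns else df[variable].notna()
    data = df[keep].copy()
    if data.empty:
        raise ValueError(f"no surviving {block} trials for {variable}")

    X, names, terms, ages = _lmm_design(data, trials[0])
    y = data[variable].to_numpy(dtype=float)
    groups = data["subject_id"].to_numpy()
    n, p = X.shape

    singular = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, X, groups=groups)
            res = model.fit(reml=True)
            sigma2 = float(res.scale)
            tau2 = float(np.asarray(res.cov_re)[0, 0])
            beta = np.asarray(res.fe_params, dtype=float)
            converged = bool(res.converged)
        except (np.linalg.LinAlgError, ValueError):
            sigma2, tau2, beta = 0.0, 0.0, np.array([])
            converged = False

    y_var = float(np.var(y)) if n > 1 else 0.0
    if not converged or sigma2 <= max(1e-10, 1e-12 * max(y_var, 1.0)):
        # Degenerate (noise-free or non-converged) fit: OLS is exact when
        # the residual variance vanishes, and a sane fallback otherwise.
        ols = sm.OLS(y, X).fit()
        beta = np.asarray(ols.params, dtype=float)
        sigma2 = float(ols.scale)
        tau2 = 0.0
        singular = True
    if tau2 < 1e-8 * max(y_var, 1.0):
        singular = True
        tau2 = max(tau2, 0.0)

    group_idx = [np.flatnonzero(groups == g) for g in pd.unique(groups)]
    sigma2_eff = max(sigma2, 1e-12)
    engine: Optional[_SatterthwaiteEngine] = None
    if opts.lmm_df_method == "satterthwaite":
        engine = _SatterthwaiteEngine(X, group_idx, sigma2_eff, tau2)
        C = engine.C
    else:
        # Cheap path: GLS covariance of beta under the fitted V, residual dfs.
        xtvx = np.zeros((p, p))
        for idx in group_idx:
            k = len(idx)
            Xi = X[idx]
            Ji = np.ones((k, k))
            Vi_inv = (np.eye(k) - (tau2 / (sigma2_eff + k * tau2)) * Ji) / sigma2_eff
            xtvx += Xi.T @ Vi_inv @ Xi
        C = np.linalg.inv(xtvx)

    def dof(L: np.ndarray) -> float:
        if engine is not None:
            return engine.df_multi(np.atleast_2d(L))
        return float(n - p)

    # Fixed-effect F tests per term
    rows = []
    for term, col_idx in terms.items():
        if not col_idx:
            continue
        L = np.zeros((len(col_idx), p))
        for r, ci in enumerate(col_idx):
            L[r, ci] = 1.0
        lam = L @ C @ L.T
        est = L @ beta
        q = L.shape[0]
        F = float(est @ np.linalg.solve(lam, est) / q) if np.linalg.det(lam) > 0 else 0.0
        df2 = dof(L)
        p_val = float(sps.f.sf(F, q, df2)) if np.isfinite(df2) else float(sps.chi2.sf(F * q, q))
        np2 = F * q / (F * q + df2) if np.isfinite(df2) and (F * q + df2) > 0 else np.nan
        rows.append({"term": term, "F": F, "df1": q, "df2": df2, "p": p_val, "partial_eta_sq": np2})
    fixed_table = pd.DataFrame(rows)

    coefficients = pd.DataFrame(
        {"name": names, "estimate": beta, "se": np.sqrt(np.clip(np.diag(C), 0, None))}
    )

    # Per-age slopes: beta_trial (+ interaction term for non-reference ages)
    slope_rows = []
    contrast_vecs: dict[str, np.ndarray] = {}
    for g in ages:
        c = np.zeros(p)
        c[names.index("trial")] = 1.0
        iname = f"trial:age[{g}]"
        if iname in names:
            c[names.index(iname)] = 1.0
        contrast_vecs[g] = c
        se = float(np.sqrt(max(c @ C @ c, 0.0)))
        nu = dof(c)
        tstat = float(c @ beta) / se if se > 0 else np.inf
        p_val = 2 * float(sps.t.sf(abs(tstat), nu)) if np.isfinite(nu) else 2 * float(sps.norm.sf(abs(tstat)))
        slope_rows.append({"age_group": g, "slope": float(c @ beta), "se": se, "df": nu, "p": p_val})
    slopes = pd.DataFrame(slope_rows)

    cont_rows = []
    pairs = list(combinations(ages, 2))
    for a, b in pairs:
        c = contrast_vecs[a] - contrast_vecs[b]
        est = float(c @ beta)
        se = float(np.sqrt(max(c @ C @ c, 0.0)))
        nu = dof(c)
        tstat = est / se if se > 0 else np.inf
        p_val = 2 * float(sps.t.sf(abs(tstat), nu)) if np.isfinite(nu) else 2 * float(sps.norm.sf(abs(tstat)))
        cont_rows.append(
            {"A": a, "B": b, "slope_diff": est, "se": se, "df": nu,
             "p": p_val, "p_bonf": min(1.0, p_val * len(pairs))}
        )
    slope_contrasts = pd.DataFrame(cont_rows)

    return LmmResult(
        fixed_table=fixed_table,
        coefficients=coefficients,
        slopes=slopes,
        slope_contrasts=slope_contrasts,
        sigma2=sigma2,
        tau2=tau2,
        n_obs=n,
        n_subjects=len(group_idx),
        converged=converged,
        singular=singular,
        df_method=opts.lmm_df_method,
        variable=variable,
        block=block,
    )
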