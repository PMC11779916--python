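"""Two-level +/-2.5 SD outlier exclusion.

Applied exactly once, in order: first per subject (individual level),
then per age group (group level). At the individual level each
non-exempt trial is compared against the leave-one-out mean and SD of
the subject's other valid non-warm-up trials; the first adaptation and
first deadaptation trials are exempt because they are expected to
diverge. At the group level all surviving trials -- including the first
(de)adaptation trials -- are compared against the group mean and SD.
Excluded trials become missing; nothing is imputed.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisOptions, Thresholds
from .containers import VARIABLES, BlockDesign

__all__ = ["individual_filter", "group_filter", "apply_outlier_filters", "exclusion_report"]

logger = logging.getLogger(__name__)


def _valid_col(variable: str) -> str:
    return {
        "peak_speed_mm_s": "valid_peak_speed",
        "movement_time_ms": "valid_movement_time",
        "movement_units": "valid_movement_units",
    }[variable]


def individual_filter(
    df: pd.DataFrame,
    variable: str,
    z_thresh: float = 2.5,
    design: Optional[BlockDesign] = None,
    leave_one_out: bool = True,
    min_trials: int = 5,
) -> pd.Series:
    """Per-subject exclusion mask (True = excluded) for one variable.

    Warm-up trials never enter any statistic and are never flagged. The
    exempt trials (first adaptation, first deadaptation) contribute to
    other trials' reference statistics but cannot themselves be
    excluded. With fewer than ``min_trials`` valid trials a subject is
    passed through unfiltered (warning logged). A zero reference SD
    excludes nothing.
    """
    design = design or BlockDesign()
    exempt = {design.first_adaptation, design.first_deadaptation}
    mask = pd.Series(False, index=df.index)
    eligible = df[_valid_col(variable)] & ~df["trial"].isin(design.warmup)

    for subject, sub in df[eligible].groupby("subject_id"):
        x = sub[variable].to_numpy(dtype=float)
        if len(x) < min_trials:
            logger.warning(
                "subject %s: only %d valid %s trials; individual filter skipped",
                subject, len(x), variable,
            )
            continue
        for row_i, (idx, trial) in enumerate(zip(sub.index, sub["trial"])):
            if trial in exempt:
                continue
            rest = np.delete(x, row_i) if leave_one_out else x
            mu, sd = rest.mean(), rest.std(ddof=1)
            if sd > 0 and abs(x[row_i] - mu) > z_thresh * sd:
                mask.loc[idx] = True
    return mask


def group_filter(
    df: pd.DataFrame,
    variable: str,
    prior_excluded: pd.Series,
    z_thresh: float = 2.5,
    design: Optional[BlockDesign] = None,
    within_age: bool = True,
    per_trial: bool = True,
) -> pd.Series:
    """Group-level exclusion mask over the trials surviving the
    individual filter. First (de)adaptation trials are eligible here.

    By default the reference statistics condition on trial position
    (each value is compared with the other subjects' values of the same
    trial), so the expected elevation of early adaptation trials is not
    itself flagged; ``per_trial=False`` pools all surviving trials.
    """
    design = design or BlockDesign()
    mask = pd.Series(False, index=df.index)
    surviving = df[_valid_col(variable)] & ~df["trial"].isin(design.warmup) & ~prior_excluded
    if not surviving.any():
        return mask
    keys: list[str] = []
    if within_age:
        keys.append("age_group")
    if per_trial:
        keys.append("trial")
    groups = df[surviving].groupby(keys) if keys else [(None, df[surviving])]
    for _, sub in groups:
        x = sub[variable].to_numpy(dtype=float)
        if len(x) < 3:
            continue
        mu, sd = x.mean(), x.std(ddof=1)
        if sd > 0:
            flag = np.abs(x - mu) > z_thresh * sd
            mask.loc[sub.index[flag]] = True
    return mask


def apply_outlier_filters(
    df: pd.DataFrame,
    thresholds: Optional[Thresholds] = None,
    options: Optional[AnalysisOptions] = None,
    design: Optional[BlockDesign] = None,
) -> pd.DataFrame:
    """Run both filter levels in order for every dependent variable.

    Adds, per variable ``v``: ``v__excl_individual``, ``v__excl_group``
    and ``v__ok`` (valid, non-warm-up, surviving both filters). The
    filters are applied exactly once each; downstream stages consume
    only the ``__ok`` columns, so masks can never resurrect trials
    invalidated upstream.
    """
    th = thresholds or Thresholds()
    opts = options or AnalysisOptions()
    design = design or BlockDesign()
    out = df.copy()
    for variable in VARIABLES:
        ind = individual_filter(
            out, variable, z_thresh=th.z_thresh, design=design,
            leave_one_out=opts.individual_leave_one_out, min_trials=th.min_trials_individual,
        )
        grp = group_filter(
            out, variable, prior_excluded=ind, z_thresh=th.z_thresh,
            design=design, within_age=opts.group_within_age, per_trial=opts.group_per_trial,
        )
        out[f"{variable}__excl_individual"] = ind
        out[f"{variable}__excl_group"] = grp
        out[f"{variable}__ok"] = (
            out[_valid_col(variable)] & ~out["trial"].isin(design.warmup) & ~ind & ~grp
        )
    return out


def exclusion_details(df: pd.DataFrame, design: Optional[BlockDesign] = None) -> pd.DataFrame:
    """Per-trial exclusion records with reason codes
    (invalid-trial / individual / group), one row per affected
    trial x variable."""
    design = design or BlockDesign()
    nonwarm = ~df["trial"].isin(design.warmup)
    rows = []
    for variable in VARIABLES:
        invalid = nonwarm & ~df[_valid_col(variable)]
        for reason, mask in (
            ("invalid-trial", invalid),
            ("individual", df[f"{variable}__excl_individual"]),
            ("group", df[f"{variable}__excl_group"]),
        ):
            for _, r in df[mask].iterrows():
                rows.append(
                    {
                        "subject_id": r["subject_id"], "age_group": r["age_group"],
                        "trial": r["trial"], "variable": variable, "reason": reason,
                        "value": r[variable],
                    }
                )
    cols = ["subject_id", "age_group", "trial", "variable", "reason", "value"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["variable", "subject_id", "trial"], kind="stable"
    ).reset_index(drop=True)


def exclusion_report(df: pd.DataFrame, design: Optional[BlockDesign] = None) -> pd.DataFrame:
    """Summary of exclusion percentages per variable and reason."""
    design = design or BlockDesign()
    nonwarm = ~df["trial"].isin(design.warmup)
    rows = []
    for variable in VARIABLES:
        n = int(nonwarm.sum())
        n_invalid = int((nonwarm & ~df[_valid_col(variable)]).sum())
        n_ind = int(df.loc[nonwarm, f"{variable}__excl_individual"].sum())
        n_grp = int(df.loc[nonwarm, f"{variable}__excl_group"].sum())
        rows.append(
            {
                "variable": variable,
                "n_trials": n,
                "n_invalid": n_invalid,
                "n_excluded_individual": n_ind,
                "n_excluded_group": n_grp,
                "pct_invalid": 100.0 * n_invalid / n if n else np.nan,
                "pct_excluded_individual": 100.0 * n_ind / n if n else np.nan,
                "pct_excluded_group": 100.0 * n_grp / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
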