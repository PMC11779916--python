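"""Per-subject (de)adaptation contrasts and trial-to-trial variability.

For each dependent variable and subject: the baseline mean (surviving
trials 3-12), the first adaptation trial (initial error vs baseline),
the mean of the last three adaptation trials (residual error,
adaptation), the first deadaptation trial (aftereffect) and the mean of
the last three deadaptation trials (residual error, deadaptation).
"Last three" means the surviving subset of those trials -- earlier
trials are never backfilled. The movement-time CV is the subject's
sample SD divided by the mean over the surviving adaptation-block
trials.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisOptions
from .containers import VARIABLES, BlockDesign

__all__ = ["summarize_subject", "movement_time_cv", "summarize_cohort"]

logger = logging.getLogger(__name__)


def _surviving(sub: pd.DataFrame, variable: str, trials: tuple[int, ...]) -> np.ndarray:
    rows = sub[sub["trial"].isin(trials) & sub[f"{variable}__ok"]]
    return rows[variable].to_numpy(dtype=float)


def summarize_subject(
    sub: pd.DataFrame, variable: str, design: Optional[BlockDesign] = None
) -> Optional[dict]:
    """Adaptation summary for one subject and variable.

    Requires the outlier masks (``__ok`` columns) to be present. Missing
    components (e.g. a group-excluded trial 13) yield NaN fields, not
    errors. Returns None -- subject dropped for this variable -- when no
    baseline trial survives.
    """
    design = design or BlockDesign()
    base = _surviving(sub, variable, design.baseline)
    if len(base) == 0:
        logger.warning(
            "subject %s: no surviving baseline trials for %s; dropped",
            sub["subject_id"].iloc[0], variable,
        )
        return None

    def single(trial: int) -> float:
        x = _surviving(sub, variable, (trial,))
        return float(x[0]) if len(x) else np.nan

    def mean_of(trials: tuple[int, ...]) -> float:
        x = _surviving(sub, variable, trials)
        return float(np.mean(x)) if len(x) else np.nan

    baseline_mean = float(np.mean(base))
    first_adapt = single(design.first_adaptation)
    last3_adapt = mean_of(design.last3_adaptation)
    first_deadapt = single(design.first_deadaptation)
    last3_deadapt = mean_of(design.last3_deadaptation)
    return {
        "subject_id": sub["subject_id"].iloc[0],
        "age_group": sub["age_group"].iloc[0],
        "variable": variable,
        "n_baseline": len(base),
        "baseline_mean": baseline_mean,
        "first_adaptation_value": first_adapt,
        "last3_adaptation_mean": last3_adapt,
        "first_deadaptation_value": first_deadapt,
        "last3_deadaptation_mean": last3_deadapt,
        "initial_error": first_adapt - baseline_mean,
        "residual_error_adaptation": last3_adapt - baseline_mean,
        "aftereffect": first_deadapt - baseline_mean,
        "residual_error_deadaptation": last3_deadapt - baseline_mean,
    }


def movement_time_cv(
    sub: pd.DataFrame, design: Optional[BlockDesign] = None, window: str = "adaptation"
) -> float:
    """Sample SD / mean of surviving movement times in the chosen window.

    NaN with fewer than two surviving values.
    """
    design = design or BlockDesign()
    if window == "adaptation":
        trials = design.adaptation
    elif window == "all":
        trials = design.baseline + design.adaptation + design.deadaptation
    else:
        raise ValueError(f"unknown CV window {window!r}")
    x = _surviving(sub, "movement_time_ms", trials)
    if len(x) < 2:
        return np.nan
    return float(np.std(x, ddof=1) / np.mean(x))


def summarize_cohort(
    df: pd.DataFrame,
    design: Optional[BlockDesign] = None,
    options: Optional[AnalysisOptions] = None,
) -> pd.DataFrame:
    """One summary row per subject x variable, with the movement-time CV
    attached to the movement-time rows."""
    design = design or BlockDesign()
    opts = options or AnalysisOptions()
    rows = []
    for _, sub in df.groupby("subject_id", sort=True):
        for variable in VARIABLES:
            summary = summarize_subject(sub, variable, design)
            if summary is None:
                continue
            if variable == "movement_time_ms":
                summary["movement_time_cv"] = movement_time_cv(sub, design, opts.cv_window)
            else:
                summary["movement_time_cv"] = np.nan
            rows.append(summary)
    return pd.DataFrame(rows)
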