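"""End-to-end orchestration: simulate (or ingest) -> preprocess ->
features -> outliers -> metrics -> stats, with artifact outputs.

Every run writes a manifest (config hash, seed, package version) next
to its CSV/JSON artifacts; identical config + seed produces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .containers import BlockDesign, MarkerTrajectory
from .events import extract_features, features_frame
from .metrics import summarize_cohort
from .outliers import apply_outlier_filters, exclusion_details, exclusion_report
from .preprocess import preprocess_trial
from .stats import CONTRAST_CELLS, AnovaResult, LmmResult, anova_cv_by_age, fit_trialwise_lmm, rm_anova_3x2
from .synth import SubjectRecord, cohort_to_long_frame, default_age_params, generate_cohort

__all__ = ["run_pipeline", "analyze_cohort", "compute_features", "read_cohort_csv", "read_c3d", "RunResult"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunResult:
    """In-memory results of a full pipeline run."""

    features: pd.DataFrame
    summary: pd.DataFrame
    exclusions: pd.DataFrame
    anovas: dict[str, AnovaResult]
    lmms: dict[str, LmmResult]
    cv_anova: Optional[AnovaResult]
    ground_truth: Optional[pd.DataFrame]
    out_dir: Optional[Path] = None


def compute_features(
    cohort: Sequence[SubjectRecord] | Sequence[tuple[str, str, list[MarkerTrajectory]]],
    config: Optional[PipelineConfig] = None,
    design: Optional[BlockDesign] = None,
) -> pd.DataFrame:
    """Preprocess every trial and extract the tidy feature table."""
    th = (config or PipelineConfig(seed=0)).thresholds
    design = design or BlockDesign()
    feats = []
    for rec in cohort:
        if isinstance(rec, SubjectRecord):
            subject_id, age_group, trials = rec.subject_id, rec.age_group, rec.trials
        else:
            subject_id, age_group, trials = rec
        for traj in trials:
            series, repaired = preprocess_trial(traj, th)
            feats.append(
                extract_features(
                    series,
                    subject_id=subject_id,
                    age_group=age_group,
                    trial=traj.trial,
                    block=design.block_of(traj.trial),
                    thresholds=th,
                    invalid_reason=repaired.invalid_reason,
                )
            )
    return features_frame(feats)


def analyze_cohort(features: pd.DataFrame, config: Optional[PipelineConfig] = None) -> RunResult:
    """Outlier filtering, adaptation summaries and the full stats layer
    on an existing feature table."""
    cfg = config or PipelineConfig(seed=0)
    design = BlockDesign()
    filtered = apply_outlier_filters(features, cfg.thresholds, cfg.options, design)
    exclusions = exclusion_report(filtered, design)
    summary = summarize_cohort(filtered, design, cfg.options)

    anovas: dict[str, AnovaResult] = {}
    for variable in ("peak_speed_mm_s", "movement_time_ms", "movement_units"):
        for contrast in CONTRAST_CELLS:
            try:
                anovas[f"{variable}/{contrast}"] = rm_anova_3x2(summary, variable, contrast)
            except ValueError as exc:
                logger.warning("ANOVA %s/%s skipped: %s", variable, contrast, exc)
    lmms: dict[str, LmmResult] = {}
    for variable in ("peak_speed_mm_s", "movement_time_ms", "movement_units"):
        for block in ("adaptation", "deadaptation"):
            try:
                lmms[f"{variable}/{block}"] = fit_trialwise_lmm(
                    filtered, variable, block, design, cfg.options
                )
            except ValueError as exc:
                logger.warning("LMM %s/%s skipped: %s", variable, block, exc)
    try:
        cv_anova = anova_cv_by_age(summary)
    except ValueError as exc:
        logger.warning("CV ANOVA skipped: %s", exc)
        cv_anova = None
    return RunResult(
        features=filtered,
        summary=summary,
        exclusions=exclusions,
        anovas=anovas,
        lmms=lmms,
        cv_anova=cv_anova,
        ground_truth=None,
    )


def _anova_to_dict(a: AnovaResult) -> dict:
    return {
        "variable": a.variable,
        "contrast": a.contrast,
        "n_subjects": a.n_subjects,
        "table": a.table.to_dict(orient="records"),
        "posthoc": a.posthoc.to_dict(orient="records") if len(a.posthoc) else [],
    }


def _lmm_to_dict(m: LmmResult) -> dict:
    return {
        "variable": m.variable,
        "block": m.block,
        "fixed_effects": m.fixed_table.to_dict(orient="records"),
        "coefficients": m.coefficients.to_dict(orient="records"),
        "slopes": m.slopes.to_dict(orient="records"),
        "slope_contrasts": m.slope_contrasts.to_dict(orient="records"),
        "sigma2": m.sigma2,
        "tau2": m.tau2,
        "n_obs": m.n_obs,
        "n_subjects": m.n_subjects,
        "converged": m.converged,
        "singular": m.singular,
        "df_method": m.df_method,
    }


def run_pipeline(config: PipelineConfig, write: bool = True) -> RunResult:
    """Execute the full pipeline from a validated configuration.

    Simulates a cohort (or ingests ``input_csv``), runs every analysis
    stage, and -- unless ``write`` is False -- writes features,
    exclusion report, per-subject summaries, a stats JSON and a run
    manifest into ``config.out_dir``.
    """
    ground_truth = None
    if config.input_csv is not None:
        cohort = read_cohort_csv(config.input_csv)
    else:
        overrides = {}
        base = default_age_params()
        for label, kv in config.cohort.age_overrides.items():
            overrides[label] = dataclasses.replace(base[label], **kv)
        params = {**base, **overrides}
        cohort = generate_cohort(
            seed=config.seed,
            group_sizes=config.cohort.group_sizes,
            age_params=params,
            noise_sd=config.cohort.noise_sd_mm,
        )
        ground_truth = pd.concat([rec.ground_truth for rec in cohort], ignore_index=True)

    features = compute_features(cohort, config)
    result = analyze_cohort(features, config)
    result.ground_truth = ground_truth

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.out_dir = out
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "config": config.model_dump(mode="json"),
            "artifacts": ["features.csv", "exclusions.csv", "summary.csv", "stats.json"],
        }
        result.features.to_csv(out / "features.csv", index=False, float_format="%.6f")
        result.exclusions.to_csv(out / "exclusions.csv", index=False, float_format="%.6f")
        exclusion_details(result.features).to_csv(
            out / "exclusion_details.csv", index=False, float_format="%.6f"
        )
        manifest["artifacts"].append("exclusion_details.csv")
        result.summary.to_csv(out / "summary.csv", index=False, float_format="%.6f")
        if ground_truth is not None:
            ground_truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.6f")
            manifest["artifacts"].append("ground_truth.csv")
        stats_payload = {
            "anovas": {k: _anova_to_dict(v) for k, v in result.anovas.items()},
            "cv_anova": _anova_to_dict(result.cv_anova) if result.cv_anova else None,
            "lmms": {k: _lmm_to_dict(v) for k, v in result.lmms.items()},
        }
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_payload, fh, indent=2, default=float, sort_keys=True)
        if config.write_trajectories and config.input_csv is None:
            cohort_to_long_frame(cohort).to_csv(
                out / "trajectories.csv", index=False, float_format="%.4f"
            )
            manifest["artifacts"].append("trajectories.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return result


def read_c3d(path: str | Path) -> None:
    """Adapter stub: C3D ingestion is deliberately out of scope."""
    raise NotImplementedError(
        "C3D ingestion is not supported; export the capture to the long CSV schema "
        "(see read_cohort_csv) instead"
    )


def read_cohort_csv(path: str | Path, fs: float = 100.0) -> list[tuple[str, str, list[MarkerTrajectory]]]:
    """Ingest a long-format cohort CSV (the synth export schema)."""
    df = pd.read_csv(path)
    required = {
        "subject_id", "age_group", "trial", "t_s",
        "mkrA_x_mm", "mkrA_y_mm", "mkrA_z_mm", "mkrB_x_mm", "mkrB_y_mm", "mkrB_z_mm",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    cohort = []
    for (subject_id, age_group), sub in df.groupby(["subject_id", "age_group"], sort=True):
        trials = []
        for trial, tr in sub.groupby("trial", sort=True):
            t = tr["t_s"].to_numpy(dtype=float)
            dt = np.diff(t)
            if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-6):
                raise ValueError(
                    f"trial {subject_id}/{trial}: non-uniform sampling; resampling is not supported"
                )
            fs_trial = 1.0 / dt[0] if len(dt) else fs
            pos_a = tr[["mkrA_x_mm", "mkrA_y_mm", "mkrA_z_mm"]].to_numpy(dtype=float)
            pos_b = tr[["mkrB_x_mm", "mkrB_y_mm", "mkrB_z_mm"]].to_numpy(dtype=float)
            missing_a = (
                tr["missing_A"].to_numpy(dtype=bool) if "missing_A" in tr else np.isnan(pos_a).any(axis=1)
            )
            missing_b = (
                tr["missing_B"].to_numpy(dtype=bool) if "missing_B" in tr else np.isnan(pos_b).any(axis=1)
            )
            trials.append(
                MarkerTrajectory(
                    t=t, pos_a=pos_a, pos_b=pos_b, fs=fs_trial,
                    missing_a=missing_a, missing_b=missing_b,
                    subject_id=str(subject_id), trial=int(trial),
                )
            )
        cohort.append((str(subject_id), str(age_group), trials))
    return cohort
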