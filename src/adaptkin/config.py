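"""Pipeline configuration: analysis thresholds and cohort parameters.

Every threshold used anywhere in the pipeline is named here once, with
its default. The kinematic event thresholds (30 mm/s onset/offset,
35 mm offset proximity window), the 8 Hz low-pass cutoff, the 500-sample
spline-fill limit and the +/-2.5 SD outlier criterion follow the study
protocol the pipeline re-implements; the remaining knobs (filter order,
movement-unit prominence floor) are documented conventions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field


class Thresholds(BaseModel):
    """All numeric analysis thresholds, in pipeline units."""

    v_on: float = Field(30.0, gt=0, description="movement-onset speed threshold, mm/s")
    v_off: float = Field(30.0, gt=0, description="movement-offset speed threshold, mm/s")
    d_max: float = Field(35.0, gt=0, description="offset proximity to max pullout, mm")
    fc_hz: float = Field(8.0, gt=0, description="Butterworth low-pass cutoff, Hz")
    filter_order: int = Field(4, ge=1, description="Butterworth order (per pass)")
    max_gap: int = Field(500, ge=1, description="max both-marker gap fillable by spline, samples")
    min_prominence: float = Field(
        10.0, ge=0, description="movement-unit peak prominence floor, mm/s (0 = literal local-maxima rule)"
    )
    edge_trim_s: float = Field(
        0.2, ge=0, description="margin cut from each trial end after filtering (zero-phase edge transients), s"
    )
    z_thresh: float = Field(2.5, gt=0, description="outlier exclusion threshold, SD units")
    min_trials_individual: int = Field(5, ge=2, description="min valid trials for individual outlier filter")


class AnalysisOptions(BaseModel):
    """Switchable interpretations where the protocol wording is ambiguous."""

    individual_leave_one_out: bool = Field(
        True, description="individual filter: leave-one-out reference stats (False = all-in)"
    )
    group_within_age: bool = Field(
        True, description="group filter statistics computed within age group (False = across all)"
    )
    group_per_trial: bool = Field(
        True,
        description=(
            "group filter statistics conditioned on trial position, so perturbed trials are "
            "compared against the group's same-trial values; False pools all surviving trials, "
            "which systematically rejects the (expectedly divergent) early adaptation trials"
        ),
    )
    cv_window: Literal["adaptation", "all"] = Field(
        "adaptation", description="block window for the movement-time CV"
    )
    lmm_df_method: Literal["satterthwaite", "residual"] = Field(
        "satterthwaite", description="denominator-df approximation for LMM F tests"
    )


class CohortSpec(BaseModel):
    """Synthetic cohort layout; sizes default to the study's final sample."""

    group_sizes: dict[str, int] = Field(default_factory=lambda: {"1.5yo": 19, "3yo": 19, "adult": 20})
    noise_sd_mm: Optional[float] = Field(None, ge=0, description="override marker noise SD for all groups")
    age_overrides: dict[str, dict[str, float]] = Field(default_factory=dict)


class PipelineConfig(BaseModel):
    """Top-level run configuration. A seed is mandatory: there is no
    silent nondeterminism anywhere in the pipeline."""

    seed: int = Field(..., ge=0, lt=2**31)
    out_dir: str = "runs/default"
    input_csv: Optional[str] = Field(None, description="analyze an existing long-format cohort CSV instead of simulating")
    input_manifest: Optional[str] = Field(None, description="cohort manifest JSON accompanying input_csv")
    cohort: CohortSpec = Field(default_factory=CohortSpec)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    options: AnalysisOptions = Field(default_factory=AnalysisOptions)
    write_trajectories: bool = Field(False, description="write the (large) long-format trajectory CSV")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in {".yml", ".yaml"} else json.load(fh)
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
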