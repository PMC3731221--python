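"""Run configuration: YAML-backed, schema-validated settings for a run."""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TrajectorySettings(_Strict):
    n_steps: int = Field(50, ge=2)
    horizon: float = Field(21.0, gt=0)
    lam1: float = Field(10.0, ge=0)
    normalization_mode: Literal["baseline", "previous_step"] = "baseline"
    cost_eval: Literal["endpoint", "substeps"] = "endpoint"
    n_substeps: int = Field(3, ge=1)
    acceptance_quantile: float = Field(0.95, gt=0, lt=1)
    acceptance_threshold: Optional[float] = None
    smoothing: float = Field(0.01, gt=0, le=1)
    max_nfev: int = Field(60, ge=1)


class BaselineSettings(_Strict):
    init_range: tuple[float, float] = (-3.0, 3.0)
    acceptance_quantile: float = Field(0.95, gt=0, lt=1)

    @model_validator(mode="after")
    def _check_range(self):
        if self.init_range[1] <= self.init_range[0]:
            raise ValueError("init_range must be increasing")
        return self


class MPSASettings(_Strict):
    alpha: float = Field(0.05, gt=0, lt=1)
    n_batches: int = Field(20, ge=1)
    batch_size: int = Field(10, ge=1)
    output: str = "output:hepatic_pool"


class AnalysisSettings(_Strict):
    low_frac: float = Field(0.1, gt=0, lt=1)
    high_frac: float = Field(0.9, gt=0, lt=1)
    n_value_bins: int = Field(50, ge=2)
    coverage: float = Field(0.95, gt=0, le=1)

    @model_validator(mode="after")
    def _check_fracs(self):
        if self.high_frac <= self.low_frac:
            raise ValueError("high_frac must exceed low_frac")
        return self


class InterventionSettings(_Strict):
    target_param: str = "k5"
    held_output: str = "hepatic_pool"
    tolerance: float = Field(1e-3, gt=0)


class RunConfig(_Strict):
    """Complete, schema-validated configuration of an ADAPT run."""

    model: str = "toy3"
    dataset: Optional[str] = None  # CSV path; None -> synthetic benchmark
    scenario: Literal["constant", "treatment"] = "treatment"
    n_iterations: int = Field(30, ge=1)
    seed: int = 0
    output_dir: str = "adapt_results"
    trajectory: TrajectorySettings = TrajectorySettings()
    baseline: BaselineSettings = BaselineSettings()
    mpsa: MPSASettings = MPSASettings()
    analysis: AnalysisSettings = AnalysisSettings()
    intervention: InterventionSettings = InterventionSettings()

    def content_hash(self) -> str:
        """Hash of the computation-relevant settings (output location excluded)."""
        payload = self.model_dump()
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.model_validate(raw)
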