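"""Analysis configuration: a validated YAML/JSON schema.

A config names the input files, the occasion-building choices, the models to
fit and the prediction scales; unknown keys are rejected so typos cannot
silently change an analysis. A single top-level seed fans out to per-model
child seeds (via numpy SeedSequence spawning) so adding a model to the list
does not perturb the randomness any other model sees.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["ModelConfig", "AnalysisConfig", "load_config", "child_seed"]


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    family: Literal["trig", "hgam", "kde"]
    periods: list[float] = Field(default_factory=lambda: [24.0, 12.0])
    covariates: list[str] = Field(default_factory=list)
    interactions: bool = False
    random_structure: Literal[
        "intercept_only",
        "intercept_plus_diagonal_slopes",
        "intercept_plus_correlated_slopes",
    ] = "intercept_only"
    quad_points: int = 11
    # hgam-specific
    K: int = 12
    knots: Optional[list[float]] = None
    structure: Literal[1, 2] = 1
    # kde-specific
    adjust: float = 1.0
    bootstrap: int = 1000


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    detections: str
    effort: str
    bin_hours: float = 1.0
    event_threshold_minutes: float = 0.0
    effort_mode: Literal["full", "any"] = "full"
    covariate: Optional[str] = None
    models: list[ModelConfig]
    scales: list[Literal["conditional", "marginal"]] = Field(
        default_factory=lambda: ["conditional"])
    ci_level: float = 0.95
    seed: int = 0
    outdir: str = "dielact_out"

    @field_validator("bin_hours")
    @classmethod
    def _bins_divide_day(cls, v):
        if abs(24.0 / v - round(24.0 / v)) > 1e-9:
            raise ValueError("bin_hours must divide 24")
        return v

    @field_validator("models")
    @classmethod
    def _unique_names(cls, v):
        names = [m.name for m in v]
        if len(set(names)) != len(names):
            raise ValueError("model names must be unique")
        return v


def load_config(path) -> AnalysisConfig:
    """Load and validate a YAML (or JSON) analysis configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return AnalysisConfig(**data)


def child_seed(seed: int, key: str) -> int:
    """Deterministic per-component seed derived from the run seed and a label."""
    h = np.frombuffer(key.encode(), dtype=np.uint8).astype(np.uint64).sum()
    ss = np.random.SeedSequence([int(seed), int(h)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
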