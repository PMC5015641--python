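"""JSON analysis configuration for the command-line pipeline."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, ValidationError, model_validator

from .classification import LLNPolicy

__all__ = ["EquationSetRef", "StrataConfig", "AnalysisConfig",
           "ConfigError", "load_analysis_config"]


class ConfigError(ValueError):
    """Invalid analysis or cohort configuration."""


class EquationSetRef(BaseModel):
    label: str
    path: str


class StrataConfig(BaseModel):
    age_bins: list[tuple[float, float]] = Field(
        default_factory=lambda: [(21.0, 65.0)])
    include_all: bool = True


class AnalysisConfig(BaseModel):
    """Everything a reporting run needs: which models, which LLN policy,
    which severity variant, which strata, and where output goes."""

    equation_sets: list[EquationSetRef]
    lln_percentile: float = 2.5
    z_limit_mode: Literal["exact", "convention"] = "convention"
    viljanen_variant: Literal["published", "harmonized"] = "published"
    strata: StrataConfig = Field(default_factory=StrataConfig)
    out_dir: str = "."
    verbosity: int = 0

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        if not self.equation_sets:
            raise ValueError("at least one equation set is required")
        labels = [e.label for e in self.equation_sets]
        if len(set(labels)) != len(labels):
            raise ValueError(f"equation-set labels must be unique, got {labels}")
        return self

    @property
    def policy(self) -> LLNPolicy:
        return LLNPolicy(percentile=self.lln_percentile,
                         z_limit_mode=self.z_limit_mode)


def _pointer(loc) -> str:
    return "/" + "/".join(str(p) for p in loc)


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Load and validate an analysis config; schema violations are
    reported with a JSON pointer to the offending field."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON: {exc}") from exc
    try:
        return AnalysisConfig.model_validate(payload)
    except ValidationError as exc:
        details = "; ".join(f"{_pointer(e['loc'])}: {e['msg']}"
                            for e in exc.errors())
        raise ConfigError(f"{path}: {details}") from exc
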