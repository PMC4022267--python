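"""Run configuration schema (YAML/JSON), validated before any computation."""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration (unknown keys, bad values, missing file)."""


class RunConfig(BaseModel):
    """User-facing knobs of a single test or evaluation run.

    Unknown keys are rejected, so typos fail loudly before computation.
    """

    model_config = ConfigDict(extra="forbid", frozen=True,
                              protected_namespaces=())

    model: Optional[str] = None
    model2: Optional[str] = None
    test: Optional[Literal["chi2", "dw", "2d-chi2-dw", "2d-chi2-chi2",
                           "lhr", "simplistic"]] = None
    case: Optional[Literal["static", "dynamic"]] = None
    dataset: Optional[str] = None
    B: int = Field(default=1000, ge=1)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    tail: Optional[Literal["right", "left", "two", "density"]] = None
    grid_n: int = Field(default=128, ge=8)
    bandwidth: str = "silverman"
    seed: int = 0
    n_datasets: int = Field(default=500, ge=10)
    out: Optional[str] = None
    log_level: str = "INFO"

    @field_validator("bandwidth")
    @classmethod
    def _bw(cls, v: str) -> str:
        if v != "silverman":
            try:
                [float(x) for x in v.split(",")]
            except ValueError:
                raise ValueError(
                    "bandwidth must be 'silverman' or 'hx,hy' floats") from None
        return v

    def bandwidth_value(self):
        if self.bandwidth == "silverman":
            return "silverman"
        parts = [float(x) for x in self.bandwidth.split(",")]
        return tuple(parts)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str) -> RunConfig:
    """Load and validate a YAML or JSON run configuration file."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"config {path} is not valid YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        return RunConfig(**raw)
    except Exception as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
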