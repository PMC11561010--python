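"""Run configuration: YAML-serialised, hashable, strict about unknown keys.

The configuration is deliberately flat and human-diffable, with keys named
after the model symbols (k_CO2, k_NPQ, j_ST0, ...) so it can be audited
against a parameter table at a glance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .model import ModelParameters
from .simulate import DEFAULT_ATOL, DEFAULT_RTOL
from .thermal import ThermalParams

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending key."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one run."""

    params: ModelParameters = field(default_factory=ModelParameters)
    scenario: str = "moderate_summer"
    scenario_overrides: dict = field(default_factory=dict)
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    t_start: float = -100.0
    t_end: float = 365.0
    output_dir: str = "."
    seed: int = 0           # fixture generation only; the model is deterministic

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        return d

    def hash(self) -> str:
        """Stable digest of the full configuration, embedded in outputs."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    params_raw = dict(raw.pop("params", {}) or {})
    thermal_raw = dict(params_raw.pop("thermal", {}) or {})
    thermal = _build(ThermalParams, thermal_raw, "params.thermal")
    params = _build(ModelParameters, {**params_raw, "thermal": thermal}, "params")
    return _build(RunConfig, {**raw, "params": params}, "config")


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
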