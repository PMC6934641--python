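"""Structured run configuration with schema validation.

A run configuration is a YAML file with nested sections mirroring the
pipeline stages; unknown keys are rejected so that typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from gatedspect.experiments import PopulationSpec
from gatedspect.gating import GateConfig
from gatedspect.projector import CDRModel, Geometry
from gatedspect.recon import ReconConfig

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a run configuration."""


@dataclass(frozen=True)
class PhaseConfig:
    amplitude_cut: float = 0.05
    bw_coverage: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude_cut < 1.0:
            raise ConfigError("amplitude_cut must be in [0, 1)")
        if not 0.0 < self.bw_coverage <= 1.0:
            raise ConfigError("bw_coverage must be in (0, 1]")


_SECTIONS = {
    "geometry": Geometry,
    "cdr": CDRModel,
    "gating": GateConfig,
    "recon": ReconConfig,
    "phase": PhaseConfig,
    "population": PopulationSpec,
}


def _build_section(cls, payload: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise ConfigError(f"unknown keys in section '{name}': {sorted(unknown)}")
    coerced = {}
    for k, v in payload.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{name}': {exc}") from exc


def _plain(v):
    """Coerce numpy scalars/sequences to plain Python for YAML output."""
    if isinstance(v, (tuple, list, np.ndarray)):
        return [_plain(x) for x in v]
    if isinstance(v, np.floating):
        return float(v)
    if isinstance(v, np.integer):
        return int(v)
    return v


@dataclass(frozen=True)
class RunConfig:
    """Validated, reproducible configuration for a full pipeline run."""

    geometry: Geometry = field(default_factory=Geometry)
    cdr: CDRModel = field(default_factory=CDRModel)
    gating: GateConfig = field(default_factory=GateConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    seed: int = 0
    dwell_time: float = 30.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration root must be a mapping")
        known = set(_SECTIONS) | {"seed", "dwell_time"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            if name in raw:
                if not isinstance(raw[name], dict):
                    raise ConfigError(f"section '{name}' must be a mapping")
                kwargs[name] = _build_section(section_cls, raw[name], name)
        if "seed" in raw:
            seed = raw["seed"]
            if not isinstance(seed, int) or seed < 0:
                raise ConfigError("seed must be a non-negative integer")
            kwargs["seed"] = seed
        if "dwell_time" in raw:
            if not isinstance(raw["dwell_time"], (int, float)) or raw["dwell_time"] <= 0:
                raise ConfigError("dwell_time must be positive")
            kwargs["dwell_time"] = float(raw["dwell_time"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        payload: dict = {"seed": self.seed, "dwell_time": self.dwell_time}
        for name in _SECTIONS:
            section = getattr(self, name)
            d = dataclasses.asdict(section)
            payload[name] = {k: _plain(v) for k, v in d.items()}
        path = Path(path)
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path
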