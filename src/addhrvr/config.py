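"""YAML run configuration: detector parameters, artifact policy, simulation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import DEFAULT_ACCEL_FLOOR, ERROR_QUANTITIES
from .epoching import ArtifactPolicy
from .simulate import PhasePlan, PlantSpec, SimConfig


class ConfigError(ValueError):
    """Configuration file contains unknown keys or out-of-range values."""


@dataclass(frozen=True)
class DetectorParams:
    epoch_length: float = 30.0
    k: float = 2.0
    min_run: int = 15
    accel_floor: float = DEFAULT_ACCEL_FLOOR
    error_quantity: str = "sem"
    max_gap: int = 0
    hour_attribution: str = "overlap"

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ConfigError("epoch_length must be > 0")
        if self.k < 0:
            raise ConfigError("k must be >= 0")
        if self.min_run < 1:
            raise ConfigError("min_run must be >= 1")
        if self.accel_floor <= 0:
            raise ConfigError("accel_floor must be > 0")
        if self.error_quantity not in ERROR_QUANTITIES:
            raise ConfigError(f"error_quantity must be one of {ERROR_QUANTITIES}")
        if self.max_gap < 0:
            raise ConfigError("max_gap must be >= 0")
        if self.hour_attribution not in ("overlap", "criterion_epoch"):
            raise ConfigError("hour_attribution must be 'overlap' or 'criterion_epoch'")


@dataclass
class RunConfig:
    detector: DetectorParams = field(default_factory=DetectorParams)
    artifacts: ArtifactPolicy = field(default_factory=ArtifactPolicy)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    log_level: str = "INFO"


def _build(cls, mapping, context: str):
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ConfigError(f"{context}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**mapping)


def _build_sim(mapping) -> SimConfig:
    if mapping is None:
        return SimConfig()
    mapping = dict(mapping)
    if "phase_plan" in mapping:
        mapping["phase_plan"] = [
            _build(PhasePlan, {**p, "accel_range": tuple(p.get("accel_range", ()))}, "sim.phase_plan")
            for p in mapping["phase_plan"]
        ]
    if "plants" in mapping:
        mapping["plants"] = [_build(PlantSpec, p, "sim.plants") for p in mapping["plants"]]
    for key in ("quiet_accel", "bout_accel", "bout_length_epochs"):
        if key in mapping:
            mapping[key] = tuple(mapping[key])
    return _build(SimConfig, mapping, "sim")


def load_config(path=None) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {"detector", "artifacts", "sim", "seed", "log_level"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
    return RunConfig(
        detector=_build(DetectorParams, raw.get("detector"), "detector"),
        artifacts=_build(ArtifactPolicy, raw.get("artifacts"), "artifacts"),
        sim=_build_sim(raw.get("sim")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
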