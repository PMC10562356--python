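"""Experiment configuration: YAML-backed, validated, losslessly round-tripping.

Every defaulted field is materialized in the resolved dump, so a bundle can
be reproduced from its resolved config alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import SimulationConfig
from .landscape import LandscapeConfig, RegionConfig
from .management import HarvestRules, SpeciesTriggers
from .weather import RCPS

__all__ = ["ExperimentConfig", "ScenarioGrid", "AttributionConfig",
           "RiskConfig", "OutputConfig", "load_config", "dump_config",
           "ConfigError"]


class ConfigError(ValueError):
    """A configuration problem, reported with the offending field path."""


@dataclass(frozen=True)
class ScenarioGrid:
    rcps: tuple[str, ...] = ("RCP4.5",)
    harvests: tuple[str, ...] = ("NoHarv", "LowHarv", "BaseHarv", "MaxHarv")

    def __post_init__(self):
        for r in self.rcps:
            if r not in RCPS:
                raise ConfigError(f"scenarios.rcps: unknown RCP {r!r}")
        for h in self.harvests:
            if h not in ("NoHarv", "LowHarv", "BaseHarv", "MaxHarv"):
                raise ConfigError(f"scenarios.harvests: unknown scenario {h!r}")


@dataclass(frozen=True)
class AttributionConfig:
    years: tuple[int, ...] = (2015, 2035, 2050)
    outputs: tuple[str, ...] = ("nbe",)
    include_noharv: bool = False


@dataclass(frozen=True)
class RiskConfig:
    variable: str = "nbe"
    years: tuple[int, ...] = (2035,)
    thresholds: tuple[float, ...] = (-1000.0,)
    level: float = 0.95


@dataclass(frozen=True)
class OutputConfig:
    directory: str = "results"
    formats: tuple[str, ...] = ("csv",)

    def __post_init__(self):
        for f in self.formats:
            if f not in ("csv", "zarr"):
                raise ConfigError(f"output.formats: unknown format {f!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    n_parameter_pool: int = 300
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scenarios: ScenarioGrid = field(default_factory=ScenarioGrid)
    rules: HarvestRules = field(default_factory=HarvestRules)
    attribution: AttributionConfig = field(default_factory=AttributionConfig)
    risk: RiskConfig = field(default_factory=RiskConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    log_level: str = "INFO"


_NESTED = {
    "landscape": LandscapeConfig,
    "simulation": SimulationConfig,
    "scenarios": ScenarioGrid,
    "rules": HarvestRules,
    "attribution": AttributionConfig,
    "risk": RiskConfig,
    "output": OutputConfig,
}


def _coerce(value, f_type, path: str):
    if dataclasses.is_dataclass(f_type) and isinstance(value, dict):
        return _build(f_type, value, path)
    if isinstance(value, list):
        return tuple(value)
    return value


def _build(dc_type, data: dict, path: str = "", strict: bool = True):
    """Instantiate a (frozen) dataclass from a mapping, flagging unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{path or dc_type.__name__}: expected a mapping")
    known = {f.name: f for f in dataclasses.fields(dc_type)}
    unknown = set(data) - set(known)
    if unknown and strict:
        raise ConfigError(f"{path or 'config'}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        sub_path = f"{path}.{name}" if path else name
        value = data[name]
        if name == "regions" and dc_type is LandscapeConfig:
            value = tuple(_build(RegionConfig, v, f"{sub_path}[{i}]")
                          for i, v in enumerate(value))
        elif name == "triggers" and dc_type is HarvestRules:
            value = tuple(_build(SpeciesTriggers, v, f"{sub_path}[{i}]")
                          for i, v in enumerate(value))
        elif name in _NESTED and dc_type is ExperimentConfig:
            value = _build(_NESTED[name], value, sub_path)
        else:
            value = _coerce(value, f.type, sub_path)
        kwargs[name] = value
    try:
        return dc_type(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path or 'config'}: {exc}") from exc


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_dict(v) for v in obj]
    return obj


def load_config(path: str | Path | None = None, data: dict | None = None,
                strict: bool = True) -> ExperimentConfig:
    """Load and validate an experiment config; defaults are resolved."""
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    return _build(ExperimentConfig, data, strict=strict)


def dump_config(config: ExperimentConfig, path: str | Path | None = None) -> str:
    """Serialize the fully resolved config (every defaulted field included)."""
    text = yaml.safe_dump(_to_dict(config), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
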