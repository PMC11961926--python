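"""Run configuration: a schema-checked YAML view of every tunable.

A run config bundles the network description, the stimulus protocol, the
stress condition, engine settings, the capacity criterion / timescale
options and an optional sweep grid. Loading is strict: unknown keys anywhere
in the document are rejected with the offending path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import types
import typing
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .analysis import CapacityCriterion
from .dynamics import (DendriteNonlinearity, NeuronParams, SpineCounts,
                       StressScaling, SynapseParams)
from .network import Connectivity, NetworkConfig
from .protocol import StimulusProtocol
from .stress import StressCondition, SweepGrid

__all__ = ["RunConfig", "load_config", "save_config", "config_hash",
           "example_config_path"]


@dataclass(frozen=True)
class TimescaleOptions:
    bin: float = 50.0  # ms
    span: float = 5000.0  # ms (clipped to the recording)
    max_lag_windows: int = 20
    scheme: str = "columns"
    sustained_only: bool = False


@dataclass(frozen=True)
class RunConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    condition: StressCondition = field(default_factory=StressCondition)
    dt: float = 0.05  # ms
    record_stride: float = 1.0  # ms
    capacity_criterion: CapacityCriterion = field(default_factory=CapacityCriterion)
    timescale: TimescaleOptions = field(default_factory=TimescaleOptions)
    sweep: SweepGrid | None = None
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.record_stride <= 0:
            raise ValueError("dt and record_stride must be positive")


class ConfigError(ValueError):
    """Raised for schema violations in a run-config document."""


def _is_dataclass_type(tp) -> bool:
    return isinstance(tp, type) and dataclasses.is_dataclass(tp)


def _unwrap_optional(tp):
    origin = typing.get_origin(tp)
    if origin in (typing.Union, types.UnionType):
        args = [a for a in typing.get_args(tp) if a is not type(None)]
        if len(args) == 1:
            return args[0]
    return tp


def _build(cls, data, path: str):
    """Recursively build a dataclass from plain dicts, rejecting unknown keys."""
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        tp = _unwrap_optional(fields[name].type)
        if isinstance(tp, str):  # postponed annotations
            tp = _RESOLVABLE.get(tp.strip(), None) or tp
        if _is_dataclass_type(tp) and isinstance(value, (dict, type(None))):
            kwargs[name] = _build(tp, value, f"{path}.{name}")
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{path}: {e}") from e


_RESOLVABLE = {
    "NetworkConfig": NetworkConfig, "Connectivity": Connectivity,
    "NeuronParams": NeuronParams, "SynapseParams": SynapseParams,
    "SpineCounts": SpineCounts, "DendriteNonlinearity": DendriteNonlinearity,
    "StimulusProtocol": StimulusProtocol, "StressCondition": StressCondition,
    "StressScaling": StressScaling, "CapacityCriterion": CapacityCriterion,
    "TimescaleOptions": TimescaleOptions, "SweepGrid": SweepGrid,
    "SweepGrid | None": SweepGrid,
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config."""
    doc = yaml.safe_load(Path(path).read_text())
    if doc is None:
        doc = {}
    return _build(RunConfig, doc, "config")


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_plain(cfg), sort_keys=True))


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the canonical JSON form of a config."""
    canon = json.dumps(_as_plain(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def example_config_path(name: str) -> Path:
    """Path of a shipped example config (control, acute_swim, chronic,
    chronic_enhanced_EE)."""
    p = Path(__file__).parent / "configs" / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(f"no shipped config named {name!r}")
    return p
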