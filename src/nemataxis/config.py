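"""Structured YAML configuration for the chemotaxis simulator.

A config file holds one block per parameter group (environment, body, gait,
behavior, model, sensory, oracle, training, simulation); any omitted key
falls back to the shipped default.  Example::

    simulation: {dt: 0.01, duration: 1200.0, seed: 7}
    environment:
      peaks: [[1.6, 0.0], [0.0, 1.6], [-1.6, 0.0], [0.0, -1.6]]
      N0: 0.008
    behavior: {C_w: 1000.0}
"""

from __future__ import annotations

from dataclasses import fields as dataclass_fields

import numpy as np
import yaml

from .behavior import BehaviorParams
from .body import BodyParams, GaitParams
from .environment import EnvironmentParams, TrueGradientParams
from .gradient_model import GradientModelParams
from .network import SensoryParams, TrainingConfig
from .pipeline import SimulationConfig

__all__ = ["load_config", "dump_config", "load_training_config"]

_BLOCKS = {
    "environment": ("environment", EnvironmentParams),
    "body": ("body", BodyParams),
    "gait": ("gait", GaitParams),
    "behavior": ("behavior", BehaviorParams),
    "model": ("model", GradientModelParams),
    "sensory": ("sensory", SensoryParams),
    "oracle": ("oracle", TrueGradientParams),
}


def _build(cls, block: dict):
    valid = {f.name for f in dataclass_fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**block)


def load_config(source) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML path, stream or dict."""
    if isinstance(source, dict):
        data = source
    else:
        if hasattr(source, "read"):
            data = yaml.safe_load(source) or {}
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh) or {}
    kwargs = dict(data.get("simulation", {}))
    for key, (attr, cls) in _BLOCKS.items():
        if key in data:
            kwargs[attr] = _build(cls, dict(data[key]))
    return SimulationConfig(**kwargs)


def load_training_config(source) -> TrainingConfig:
    """Build a :class:`TrainingConfig` from a YAML path, stream or dict."""
    if isinstance(source, dict):
        data = source
    else:
        if hasattr(source, "read"):
            data = yaml.safe_load(source) or {}
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh) or {}
    block = data.get("training", data)
    block = {k: v for k, v in dict(block).items()}
    if "train_window" in block:
        block["train_window"] = tuple(block["train_window"])
    if "validation_window" in block:
        block["validation_window"] = tuple(block["validation_window"])
    return _build(TrainingConfig, block)


def _plain(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, tuple):
        return [_plain(v) for v in value]
    return value


def dump_config(config: SimulationConfig) -> str:
    """Serialise a config back to YAML (inverse of :func:`load_config`)."""
    data: dict = {"simulation": {}}
    for f in dataclass_fields(SimulationConfig):
        value = getattr(config, f.name)
        if f.name in {attr for attr, _ in _BLOCKS.values()}:
            block_key = next(k for k, (attr, _) in _BLOCKS.items() if attr == f.name)
            data[block_key] = {
                g.name: _plain(getattr(value, g.name)) for g in dataclass_fields(type(value))
            }
        else:
            data["simulation"][f.name] = _plain(value)
    return yaml.safe_dump(data, sort_keys=False)
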