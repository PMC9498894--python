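"""YAML configuration files for model runs and simulations.

A model config file is a flat mapping of :class:`~multiconv.model.ModelConfig`
field names; a grid file maps field names to lists of values (the cartesian
product is expanded).  A simulation spec file looks like::

    n_sequences: 2000
    seq_length: 150
    noise_sd: 0.5
    plant_probability: 0.8
    intercept: 0.0
    motifs:
      - consensus: TGACTCAGCAGT
        weight: 1.0
        concentration: 0.85
"""

from __future__ import annotations

import itertools
from dataclasses import fields
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .model import ModelConfig
from .simulate import SimulationSpec, consensus_motif

__all__ = [
    "load_model_config",
    "load_model_grid",
    "load_simulation_spec",
]

_MODEL_FIELDS = {f.name for f in fields(ModelConfig)}


def _read_yaml(path: str | Path) -> dict:
    with open(path) as handle:
        payload = yaml.safe_load(handle)
    if payload is None:
        return {}
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: expected a YAML mapping at the top level")
    return payload


def _check_model_keys(payload: dict, path) -> None:
    unknown = set(payload) - _MODEL_FIELDS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")


def load_model_config(path: str | Path, **overrides) -> ModelConfig:
    """Load a flat ModelConfig mapping; keyword overrides win."""
    payload = _read_yaml(path)
    _check_model_keys(payload, path)
    payload.update(overrides)
    return ModelConfig(**payload)


def load_model_grid(path: str | Path) -> list[ModelConfig]:
    """Load a grid file (values may be lists) into the product of configs."""
    payload = _read_yaml(path)
    _check_model_keys(payload, path)
    keys = list(payload)
    value_lists = [
        v if isinstance(v, list) else [v] for v in (payload[k] for k in keys)
    ]
    configs = []
    for combo in itertools.product(*value_lists):
        configs.append(ModelConfig(**dict(zip(keys, combo))))
    if not configs:
        raise ConfigError(f"{path}: empty grid")
    return configs


def load_simulation_spec(path: str | Path, **overrides) -> SimulationSpec:
    """Load a simulation spec; planted motifs are given by consensus strings."""
    payload = _read_yaml(path)
    motif_entries = payload.pop("motifs", [])
    planted = []
    for entry in motif_entries:
        if "consensus" not in entry or "weight" not in entry:
            raise ConfigError(f"{path}: each motif needs 'consensus' and 'weight'")
        motif = consensus_motif(
            entry["consensus"],
            concentration=float(entry.get("concentration", 0.85)),
            name=entry.get("name"),
        )
        planted.append((motif, float(entry["weight"])))
    payload["planted_motifs"] = planted
    payload.update(overrides)
    try:
        return SimulationSpec(**payload)
    except TypeError as err:
        raise ConfigError(f"{path}: {err}") from err
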