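"""Structured configuration: parameter blocks, scenario presets, YAML round-trip.

The config file is a flat, versioned YAML document with one block per
parameter group (absorption, hepatic, peripheral, secretion, renal, solver,
scenario).  Every kinetic constant of the model appears with an explicit
default; unknown keys are rejected by name and a loaded config saves back
byte-identically (round-trip identity).

Constants whose printed source values are unit-ambiguous carry their
calibrated per-minute interpretation here; the calibration is described in
docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import species as sp
from .engine import GavageProtocol, ModelParameters, Scenario, SolverSettings
from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config", "save_config", "scenario_presets"]

SCHEMA_VERSION = 1

_BLOCKS = {
    "absorption": sp.AbsorptionParameters,
    "hepatic": sp.HepaticKinetics,
    "peripheral": sp.PeripheralKinetics,
    "secretion": sp.SecretionParameters,
    "renal": sp.RenalParameters,
    "solver": SolverSettings,
}


@dataclass
class RunConfig:
    """A full, validated run configuration."""

    params: ModelParameters = field(default_factory=ModelParameters)
    scenario: Scenario = field(default_factory=Scenario)
    solver: SolverSettings = field(default_factory=SolverSettings)
    schema_version: int = SCHEMA_VERSION


def _block_to_dict(obj: Any) -> dict[str, Any]:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}


def _block_from_dict(cls: type, data: dict[str, Any], block: str) -> Any:
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(f"unknown key(s) in '{block}': {sorted(unknown)}")
    for key, value in data.items():
        if not isinstance(value, (int, float, str, bool)):
            raise ConfigurationError(f"'{block}.{key}': expected a scalar, got {type(value).__name__}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigurationError(f"invalid block '{block}': {exc}") from exc


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    d: dict[str, Any] = {"schema_version": cfg.schema_version}
    for name, _ in _BLOCKS.items():
        obj = cfg.solver if name == "solver" else getattr(cfg.params, name)
        d[name] = _block_to_dict(obj)
    sc = _block_to_dict(cfg.scenario)
    sc["gavage"] = _block_to_dict(cfg.scenario.gavage)
    sc["overrides"] = {path: value for path, value in cfg.scenario.overrides}
    d["scenario"] = sc
    return d


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    data = dict(data)
    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigurationError(f"unsupported schema_version {version}")
    known = set(_BLOCKS) | {"scenario"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")

    blocks: dict[str, Any] = {}
    for name, cls in _BLOCKS.items():
        blocks[name] = _block_from_dict(cls, data.get(name, {}), name)

    sc_data = dict(data.get("scenario", {}))
    gav = GavageProtocol(**sc_data.pop("gavage", {}))
    overrides = tuple(sorted((str(k), float(v)) for k, v in sc_data.pop("overrides", {}).items()))
    sc_fields = {f.name for f in dataclasses.fields(Scenario)} - {"gavage", "overrides"}
    unknown = set(sc_data) - sc_fields
    if unknown:
        raise ConfigurationError(f"unknown key(s) in 'scenario': {sorted(unknown)}")
    scenario = Scenario(gavage=gav, overrides=overrides, **sc_data)

    params = ModelParameters(
        absorption=blocks["absorption"],
        hepatic=blocks["hepatic"],
        peripheral=blocks["peripheral"],
        secretion=blocks["secretion"],
        renal=blocks["renal"],
    )
    return RunConfig(params=params, scenario=scenario, solver=blocks["solver"])


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; missing blocks use defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config; load(save(load(x))) is the identity."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def scenario_presets() -> dict[str, Scenario]:
    """The three headline scenarios and their parameter deltas.

    normal     : healthy subject, high GLP-1 glucose sensitivity (50),
                 paracellular permeability 0.15 um/s, shunt nearly closed.
    low_glp1   : GLP-1-deficient secretion (sensitivity 0.1), otherwise normal.
    nash_shunt : NASH with portosystemic shunting -- shunt wide open
                 (0.005 mm Hg.s/ml) and presinusoidal resistance raised
                 four-fold (0.020 mm Hg.s/ml).
    """
    normal = Scenario()
    return {
        "normal": normal,
        "low_glp1": dataclasses.replace(normal, glp1_glucose_sensitivity=0.1),
        "nash_shunt": dataclasses.replace(
            normal, pss_resistance=0.005, presinusoidal_resistance=0.020
        ),
    }
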