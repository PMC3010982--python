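"""Configuration schema: one structured YAML file drives everything.

Every parameter has a default; an empty file (or no file) yields the
default configuration.  Unknown keys are an error — configs are never
silently ignored — and every constraint violation is reported with the
offending key.  The kinetic, field and world constants in the default
configuration are this package's own calibration (the scheme they
reconstruct was never published with numeric values); see
``docs/methods.md`` for how they were chosen and what they are meant to
reproduce.
"""

from __future__ import annotations

import copy
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError, ParameterError
from .microenvironment import FieldParams
from .model_core import NoiseParams, PhenotypeParams
from .motility import MotilityParams, PopulationParams
from .simulator import SimulationConfig, SweepSettings

__all__ = ["DEFAULTS", "default_config", "parse_config", "config_to_dict"]

DEFAULTS: dict[str, dict[str, Any]] = {
    "phenotype": {"A": 10.0, "B": 50.0, "n": 2, "k_deg": 0.2, "C_B": 15.0},
    "noise": {"N_int": 0.1, "N_ext": 3.0},
    "motility": {
        "r_align": 1.5,
        "eta": 0.2,
        "mean_speed": 0.5,
        "alignment_enabled": True,
        "polar": False,
    },
    "population": {
        "cycle_min": 20,
        "cycle_max": 24,
        "crowding_cap": 26,
        "crowd_radius": 2,
        "R_div": 27.0,
        "death_rate": 0.002,
    },
    "field": {"R0": 100.0, "D_med": 0.1, "D_lat": 0.2, "u": 4.89, "patch_size": 1.0},
    "world": {"nx": 60, "ny": 60},
    "run": {
        "n_founders": 24,
        "founder_init": "mixed",
        "n_steps": 220,
        "record_steps": [40, 100],
        "seed": 0,
    },
    "sweep": {"B_frozen": 525.0, "eps_conv": 0.01, "delta_tol": 0.02},
}

_SECTION_TYPES = {
    "phenotype": PhenotypeParams,
    "noise": NoiseParams,
    "motility": MotilityParams,
    "population": PopulationParams,
    "field": FieldParams,
    "sweep": SweepSettings,
}


def _merge(user: Mapping[str, Any]) -> dict[str, dict[str, Any]]:
    merged = copy.deepcopy(DEFAULTS)
    for section, content in user.items():
        if section not in merged:
            raise ConfigurationError(f"unknown config section {section!r}")
        if content is None:
            continue
        if not isinstance(content, Mapping):
            raise ConfigurationError(f"config section {section!r} must be a mapping")
        for key, value in content.items():
            if key not in merged[section]:
                raise ConfigurationError(f"unknown config key {section}.{key!r}")
            merged[section][key] = value
    return merged


def _build(merged: dict[str, dict[str, Any]]) -> SimulationConfig:
    parts: dict[str, Any] = {}
    for section, cls in _SECTION_TYPES.items():
        try:
            parts[section] = cls(**merged[section])
        except (ParameterError, ConfigurationError, TypeError) as exc:
            raise ConfigurationError(f"invalid config section {section!r}: {exc}") from exc
    run = merged["run"]
    world = merged["world"]
    try:
        return SimulationConfig(
            phenotype=parts["phenotype"],
            noise=parts["noise"],
            motility=parts["motility"],
            population=parts["population"],
            field=parts["field"],
            nx=int(world["nx"]),
            ny=int(world["ny"]),
            n_founders=int(run["n_founders"]),
            founder_init=str(run["founder_init"]),
            n_steps=int(run["n_steps"]),
            record_steps=tuple(int(s) for s in run["record_steps"]),
            seed=int(run["seed"]),
            sweep=parts["sweep"],
        )
    except (ParameterError, ConfigurationError) as exc:
        raise ConfigurationError(str(exc)) from exc


def default_config(**run_overrides: Any) -> SimulationConfig:
    """The frozen default configuration, optionally with run.* overrides."""
    merged = copy.deepcopy(DEFAULTS)
    for key, value in run_overrides.items():
        if key not in merged["run"]:
            raise ConfigurationError(f"unknown run key {key!r}")
        merged["run"][key] = value
    return _build(merged)


def parse_config(path: str | Path | None) -> SimulationConfig:
    """Load, merge with defaults, and validate a YAML configuration.

    ``None`` or the literal string "default" returns the default
    configuration.  An empty file does the same.
    """
    if path is None or str(path) == "default":
        return _build(copy.deepcopy(DEFAULTS))
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file {path} does not exist")
    try:
        user = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
    if user is None:
        user = {}
    if not isinstance(user, Mapping):
        raise ConfigurationError(f"config root in {path} must be a mapping")
    return _build(_merge(user))


def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    """Flatten a SimulationConfig back into the YAML section layout."""
    return {
        "phenotype": asdict(config.phenotype),
        "noise": asdict(config.noise),
        "motility": asdict(config.motility),
        "population": asdict(config.population),
        "field": asdict(config.field),
        "world": {"nx": config.nx, "ny": config.ny},
        "run": {
            "n_founders": config.n_founders,
            "founder_init": config.founder_init,
            "n_steps": config.n_steps,
            "record_steps": list(config.record_steps),
            "seed": config.seed,
        },
        "sweep": asdict(config.sweep),
    }
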