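"""Simulation configuration: schema, YAML serialisation and presets.

A configuration fully parameterises one simulated life: the mutation DFE,
the microenvironment, the demography schedules, the lifespan, the clone
threshold and the seed. All randomness flows from the single top-level
seed, expanded inside the engine into independent named streams. Configs
round-trip losslessly through plain-text YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .constants import DEFAULT_LIFESPAN_WEEKS, calibrated_tier3_rate
from .demography import Schedules, schedules_from_preset
from .dfe import DFESpec
from .errors import ConfigError, ParameterError
from .microenvironment import EnvSpec

_INITIAL_CLONE_MODES = ("per_cell", "single")


@dataclass(frozen=True)
class SimulationConfig:
    """Complete parameterisation of one simulation run."""

    dfe: DFESpec = field(default_factory=DFESpec)
    env: EnvSpec = field(default_factory=EnvSpec)
    schedules: Schedules = field(default_factory=Schedules)
    lifespan_weeks: int = DEFAULT_LIFESPAN_WEEKS
    initial_cells: int = 300
    clone_threshold: float = 0.05
    seed: int = 0
    record_cadence: int = 1
    initial_clones: str = "per_cell"
    symmetric_division: bool = False
    preset_name: str | None = None

    def __post_init__(self) -> None:
        if self.lifespan_weeks < 0:
            raise ConfigError(f"lifespan_weeks must be >= 0, got {self.lifespan_weeks}")
        if self.initial_cells <= 0:
            raise ConfigError(f"initial_cells must be positive, got {self.initial_cells}")
        if self.clone_threshold <= 0:
            raise ConfigError(
                f"clone_threshold must be > 0, got {self.clone_threshold}"
            )
        if self.record_cadence < 1:
            raise ConfigError(f"record_cadence must be >= 1, got {self.record_cadence}")
        if self.initial_clones not in _INITIAL_CLONE_MODES:
            raise ConfigError(
                f"initial_clones must be one of {_INITIAL_CLONE_MODES}, "
                f"got {self.initial_clones!r}"
            )


# -- dict / YAML round trip --------------------------------------------------


def _spec_to_dict(spec) -> dict:
    return dataclasses.asdict(spec)


def config_to_dict(config: SimulationConfig) -> dict:
    out = {
        "preset": config.preset_name,
        "lifespan_weeks": config.lifespan_weeks,
        "initial_cells": config.initial_cells,
        "clone_threshold": config.clone_threshold,
        "seed": config.seed,
        "record_cadence": config.record_cadence,
        "initial_clones": config.initial_clones,
        "symmetric_division": config.symmetric_division,
        "dfe": _spec_to_dict(config.dfe),
        "environment": _spec_to_dict(config.env),
        "demography": _spec_to_dict(config.schedules),
    }
    return out


def _build_section(cls, data: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"{section}: unknown field(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except (ParameterError, ConfigError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a validated config from a plain dict, filling defaults.

    A ``preset`` key seeds all fields from the named preset; any other keys
    override it. Validation errors name the offending field path.
    """
    data = dict(data or {})
    preset = data.pop("preset", None)
    base = get_preset(preset) if preset else SimulationConfig()

    kwargs: dict = {}
    if "dfe" in data:
        merged = {**_spec_to_dict(base.dfe), **(data.pop("dfe") or {})}
        kwargs["dfe"] = _build_section(DFESpec, merged, "dfe")
    if "environment" in data:
        merged = {**_spec_to_dict(base.env), **(data.pop("environment") or {})}
        kwargs["env"] = _build_section(EnvSpec, merged, "environment")
    if "demography" in data:
        demo = dict(data.pop("demography") or {})
        demo_preset = demo.pop("preset", None)
        if demo_preset:
            sched = schedules_from_preset(demo_preset)
        else:
            sched = base.schedules
        merged = {**_spec_to_dict(sched), **demo}
        kwargs["schedules"] = _build_section(Schedules, merged, "demography")

    top_fields = {
        "lifespan_weeks", "initial_cells", "clone_threshold", "seed",
        "record_cadence", "initial_clones", "symmetric_division",
    }
    unknown = set(data) - top_fields
    if unknown:
        raise ConfigError(f"unknown top-level field(s) {sorted(unknown)}")
    kwargs.update(data)
    try:
        return replace(base, preset_name=preset, **kwargs)
    except (ParameterError, ConfigError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    return config_from_dict(data or {})


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a config as YAML; load(save(c)) reproduces ``c`` exactly."""
    with open(path, "w") as handle:
        yaml.safe_dump(config_to_dict(config), handle, sort_keys=True)


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of the full configuration, for run metadata."""
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# -- presets -----------------------------------------------------------------


def preset_catalog() -> dict[str, SimulationConfig]:
    """Named replication presets.

    * ``mutations_only`` — stable 11,000-cell adult pool, mutation positive
      tail 1%, environment disabled.
    * ``composite`` — same demography with the bicomponent microenvironment
      enabled (symmetric distributed component) and mutation positive
      tail 0%, the configuration contrasted against mutations-only.
    * ``slow_cycle`` — mutations-only with the adult division rate lowered
      to 0.6 divisions/year (Tier-3 rate recalibrated to the reference
      slope at that rate), mutation tail 1%.
    * ``pool_11k`` / ``pool_11k_to_25k`` — stable 11,000-cell and growing
      11,000 -> 25,000-cell adult-pool variants, mutation tail 1%.
    """
    stable = schedules_from_preset("stable")
    slow = schedules_from_preset("slow")
    growing = schedules_from_preset("growing")
    return {
        "mutations_only": SimulationConfig(
            dfe=DFESpec(positive_tail_fraction=0.01),
            env=EnvSpec(enabled=False),
            schedules=stable,
            preset_name="mutations_only",
        ),
        "composite": SimulationConfig(
            dfe=DFESpec(positive_tail_fraction=0.0),
            env=EnvSpec(enabled=True, positive_tail_fraction=0.5),
            schedules=stable,
            preset_name="composite",
        ),
        "slow_cycle": SimulationConfig(
            dfe=DFESpec(
                positive_tail_fraction=0.01,
                tier3_rate_per_division=calibrated_tier3_rate(slow.adult_division_rate),
            ),
            env=EnvSpec(enabled=False),
            schedules=slow,
            preset_name="slow_cycle",
        ),
        "pool_11k": SimulationConfig(
            dfe=DFESpec(positive_tail_fraction=0.01),
            env=EnvSpec(enabled=False),
            schedules=stable,
            preset_name="pool_11k",
        ),
        "pool_11k_to_25k": SimulationConfig(
            dfe=DFESpec(positive_tail_fraction=0.01),
            env=EnvSpec(enabled=False),
            schedules=growing,
            preset_name="pool_11k_to_25k",
        ),
    }


def get_preset(name: str) -> SimulationConfig:
    """Fetch a named preset configuration."""
    catalog = preset_catalog()
    try:
        return catalog[name]
    except KeyError:
        raise ConfigError(
            f"preset: unknown preset {name!r}; known: {sorted(catalog)}"
        ) from None
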