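"""Structured run configuration: one YAML file, strict schema.

Keys carry units in their names.  Unknown keys are rejected (typo guard)
and every violation is reported, not just the first.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .phantom import PhantomConfig

__all__ = ["RunConfig", "parse_config", "ConfigError"]


class ConfigError(ValueError):
    """Configuration file violates the schema; message lists all problems."""


_SCHEMA: dict[str, type] = {
    "histories": int,
    "seed": int,
    "source_energy_MeV": float,
    "outer_radius_cm": float,
    "bone_distance_cm": float,
    "bone_thickness_cm": float,
    "tally_min_cm": float,
    "tally_max_cm": float,
    "ebin_width_MeV": float,
    "n_batches": int,
}

_DEFAULTS = {
    "source_energy_MeV": 0.662,
    "outer_radius_cm": 15.0,
    "bone_distance_cm": None,
    "bone_thickness_cm": None,
    "tally_min_cm": 0.1,
    "tally_max_cm": 10.0,
    "ebin_width_MeV": 0.010,
    "n_batches": 20,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated simulation settings: phantom geometry plus run controls."""

    phantom: PhantomConfig
    histories: int
    seed: int
    ebin_width: float
    n_batches: int


def parse_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    problems = []
    for key in raw:
        if key not in _SCHEMA:
            problems.append(f"unknown key {key!r}")
    for key in ("histories", "seed"):
        if key not in raw:
            problems.append(f"missing required key {key!r}")
    merged = {**_DEFAULTS, **{k: v for k, v in raw.items() if k in _SCHEMA}}
    for key, typ in _SCHEMA.items():
        val = merged.get(key)
        if val is None:
            continue
        if typ is float and isinstance(val, int):
            val = float(val)
        if not isinstance(val, typ) or isinstance(val, bool):
            problems.append(f"key {key!r} must be {typ.__name__}, got {val!r}")
            continue
        merged[key] = val
    if not problems:
        if merged["histories"] < 1:
            problems.append("histories must be >= 1")
        if not (0 <= merged["seed"] < 2**31):
            problems.append("seed must be a non-negative 31-bit integer")
        for key in ("bone_distance_cm", "bone_thickness_cm",
                    "ebin_width_MeV", "source_energy_MeV"):
            v = merged[key]
            if v is not None and v <= 0:
                problems.append(f"{key} must be positive, got {v}")
    if problems:
        raise ConfigError(f"{path}: " + "; ".join(problems))
    try:
        phantom = PhantomConfig(
            outer_radius=merged["outer_radius_cm"],
            source_energy=merged["source_energy_MeV"],
            bone_distance=merged["bone_distance_cm"],
            bone_thickness=merged["bone_thickness_cm"],
            tally_range=(merged["tally_min_cm"], merged["tally_max_cm"]),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return RunConfig(
        phantom=phantom,
        histories=merged["histories"],
        seed=merged["seed"],
        ebin_width=merged["ebin_width_MeV"],
        n_batches=merged["n_batches"],
    )
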