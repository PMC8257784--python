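"""Configuration schema, validation, and deterministic seed derivation.

A run is configured by one YAML file with up to five sections (one per
pipeline stage); an empty file means "all defaults".  Unknown keys are
rejected with the offending key named.  Randomness flows from one master
seed: each stage derives its own stream as ``SeedSequence([master, code])``
with a fixed per-stage code, and per-item streams append the item index,
so any stage is reproducible in isolation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .exceptions import ConfigError

__all__ = ["load_config", "save_config", "default_config", "stage_seed", "stage_rng", "STAGE_CODES"]

#: Fixed per-stage codes for seed derivation (the documented counter scheme).
STAGE_CODES = {
    "simulate": 1,
    "analyze": 2,
    "sweep": 3,
    "behavior": 4,
    "morpho": 5,
}

# schema: section -> key -> (default, validator, description-of-constraint)
_POS = ("must be positive", lambda v: v > 0)
_NONNEG = ("must be non-negative", lambda v: v >= 0)
_PROB = ("must be in [0, 1]", lambda v: 0.0 <= v <= 1.0)
_POSINT = ("must be a positive integer", lambda v: isinstance(v, int) and v > 0)
_ANY = ("", lambda v: True)

_SCHEMA = {
    "seed": {"__scalar__": (0, ("must be an integer", lambda v: isinstance(v, int)))},
    "generator": {
        "firing_rate_hz": (45.2, _POS),
        "isi_cv": (0.5, _NONNEG),
        "duration_s": (60.0, _POS),
        "failure_prob": (0.00607, _PROB),
        "swelling_failure_prob": (0.00112, _PROB),
        "delay_ms": (0.2, _ANY),
        "delay_jitter_ms": (0.05, _NONNEG),
    },
    "simulate": {
        "n_control": (11, _POSINT),
        "n_swelling": (9, _POSINT),
    },
    "analyze": {
        "window_ms": (2.0, _POS),
        "bin_hz": (20.0, _POS),
    },
    "sweep": {
        "fractions": ([0.0, 0.25, 0.5, 0.75, 1.0], ("must be a list of values in [0, 1]",
                      lambda v: isinstance(v, list) and all(0.0 <= x <= 1.0 for x in v))),
        "n_outer": (100, _POSINT),
        "cohort_size": (40, _POSINT),
        "n_reps": (5000, _POSINT),
        "duration_s": (1.0, _POS),
        "mapping_slope": (1.0, _ANY),
        "mapping_intercept": (0.0, _ANY),
        "predictor": ("transmitted_fraction", ("must be 'transmitted_fraction' or 'pct_swelling'",
                      lambda v: v in ("transmitted_fraction", "pct_swelling"))),
    },
    "behavior": {
        "n_animals": (21, ("must be an integer >= 3", lambda v: isinstance(v, int) and v >= 3)),
        "task": ("rotarod", ("must be one of rotarod/erasmus/vor",
                 lambda v: v in ("rotarod", "erasmus", "vor"))),
        "density_mean": (35.0, ("must be in [0, 100]", lambda v: 0.0 <= v <= 100.0)),
        "density_sd": (8.0, _NONNEG),
        "slope": (2.0, _ANY),
        "intercept": (30.0, _ANY),
        "noise_sd": (20.0, _NONNEG),
    },
    "morpho": {
        "conditions": (["low_ttx", "no_ttx", "high_ttx"], ("must be a list",
                       lambda v: isinstance(v, list) and len(v) >= 1)),
        "dispersion": (0.3, _NONNEG),
        "g_ratio_convention": ("standard", ("must be 'standard' or 'sum_form'",
                               lambda v: v in ("standard", "sum_form"))),
    },
}


def default_config() -> dict:
    """The full configuration with every documented default filled in."""
    out = {}
    for section, keys in _SCHEMA.items():
        if "__scalar__" in keys:
            out[section] = keys["__scalar__"][0]
        else:
            out[section] = {k: default for k, (default, _) in keys.items()}
    return out


def _validate_section(section: str, values: dict) -> dict:
    schema = _SCHEMA[section]
    out = {k: default for k, (default, _) in schema.items()}
    for key, value in values.items():
        if key not in schema:
            raise ConfigError(f"unknown key '{section}.{key}'")
        default, (msg, check) = schema[key]
        if isinstance(default, float) and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        if type(default) is not type(value) and not isinstance(value, type(default)):
            raise ConfigError(
                f"'{section}.{key}' has wrong type {type(value).__name__}"
            )
        if not check(value):
            raise ConfigError(f"'{section}.{key}' {msg} (got {value!r})")
        out[key] = value
    return out


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> dict:
    """Load and validate a YAML configuration.

    Missing file or empty file yields all defaults; unknown sections or
    keys raise :class:`ConfigError` naming the offender.  ``overrides``
    (e.g. a command-line seed) are applied after file values.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration root must be a mapping")
    if overrides:
        raw = {**raw, **overrides}

    out = default_config()
    for section, values in raw.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown section '{section}'")
        if "__scalar__" in _SCHEMA[section]:
            default, (msg, check) = _SCHEMA[section]["__scalar__"]
            if not check(values):
                raise ConfigError(f"'{section}' {msg} (got {values!r})")
            out[section] = values
        else:
            if not isinstance(values, dict):
                raise ConfigError(f"section '{section}' must be a mapping")
            out[section] = _validate_section(section, values)
    return out


def save_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True), encoding="utf-8")


def stage_seed(master_seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    """Deterministic per-stage (and per-item) seed sequence."""
    if stage not in STAGE_CODES:
        raise ConfigError(f"unknown stage '{stage}'")
    return np.random.SeedSequence([int(master_seed), STAGE_CODES[stage], int(index)])


def stage_rng(master_seed: int, stage: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage, index))
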