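"""Readers/writers for the package's CSV dialects and run configuration.

Concentration–time datasets use a NONMEM-style layout (ID, TIME, AMT,
RATE, DV, EVID, MDV plus optional covariate columns); covariate tables use
a flat per-subject layout. Run configurations are YAML/JSON mappings
validated against a fixed key schema before any computation.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_nonmem",
    "write_nonmem",
    "read_covariates",
    "write_covariates",
    "load_config",
    "ConfigError",
]

NONMEM_REQUIRED = ("ID", "TIME", "AMT", "DV", "EVID")
COVARIATE_COLUMNS = (
    "id",
    "age",
    "sex",
    "weight_kg",
    "height_cm",
    "scr_mg_dl",
    "cysc_mg_l",
)


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


def read_nonmem(path) -> pd.DataFrame:
    """Read a NONMEM-style CSV, checking the required column set."""
    df = pd.read_csv(path)
    missing = [c for c in NONMEM_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"dataset {path!s} is missing required columns: {missing}")
    return df


def write_nonmem(df: pd.DataFrame, path) -> None:
    missing = [c for c in NONMEM_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    df.to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    """Read a per-subject covariate table (id, age, sex, weight_kg, ...)."""
    df = pd.read_csv(path)
    missing = [c for c in COVARIATE_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table {path!s} is missing columns: {missing}")
    return df


def write_covariates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# keys accepted in a simulate-pta run configuration, with expected types
_CONFIG_SCHEMA: dict[str, type | tuple[type, ...]] = {
    "n": int,
    "seed": int,
    "ld_set": list,
    "md_set": list,
    "md_interval": (int, float),
    "infusion_duration": (int, float),
    "trough_thresholds": list,
    "mics": list,
    "weight_mean": (int, float),
    "weight_cv": (int, float),
    "egfr_mean": (int, float),
    "egfr_cv": (int, float),
    "egfr_bounds": list,
    "weight_bounds": list,
    "model": (str, dict),
}


def load_config(path) -> dict:
    """Load and validate a YAML/JSON run configuration.

    Unknown or mistyped keys raise :class:`ConfigError` naming every
    offending key, so a typo cannot silently fall back to a default.
    """
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if payload is None:
        return {}
    if not isinstance(payload, dict):
        raise ConfigError(f"config {path!s} must be a mapping")
    bad = sorted(set(payload) - set(_CONFIG_SCHEMA))
    if bad:
        raise ConfigError(f"unknown config keys: {bad}")
    mistyped = [
        k for k, v in payload.items() if not isinstance(v, _CONFIG_SCHEMA[k])
    ]
    if mistyped:
        raise ConfigError(f"config keys with invalid types: {sorted(mistyped)}")
    return payload


def ensure_outdir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out
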