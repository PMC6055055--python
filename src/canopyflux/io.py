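"""CSV/JSON/YAML readers and writers for the pipeline's tabular artifacts.

All tables travel as plain CSV with the documented column sets; configuration
(leaf parameters, chamber system, canopy state) as YAML or JSON mappings.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .chamber import CHAMBER_COLUMNS, SystemConfig
from .leaf import LeafParams
from .structure import PROFILE_COLUMNS, CanopyState
from .synthetic import WEATHER_COLUMNS

__all__ = [
    "read_chamber_log",
    "read_weather",
    "read_profile",
    "write_table",
    "load_leaf_params",
    "load_system_config",
    "load_canopy_state",
    "write_json",
]


def _read_checked(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_chamber_log(path) -> pd.DataFrame:
    """Chamber logger CSV: one row per record, columns per CHAMBER_COLUMNS."""
    return _read_checked(path, CHAMBER_COLUMNS)


def read_weather(path) -> pd.DataFrame:
    """Weather CSV with columns per WEATHER_COLUMNS."""
    return _read_checked(path, WEATHER_COLUMNS)


def read_profile(path) -> pd.DataFrame:
    """Layered canopy profile CSV with columns per PROFILE_COLUMNS."""
    return _read_checked(path, PROFILE_COLUMNS)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _load_mapping(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_leaf_params(path) -> LeafParams:
    return LeafParams(**_load_mapping(path))


def load_system_config(path) -> SystemConfig:
    return SystemConfig(**_load_mapping(path))


def load_canopy_state(path) -> CanopyState:
    return CanopyState(**_load_mapping(path))


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
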