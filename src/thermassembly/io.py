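"""Trait-table and temperature-log I/O, configs, and run manifests.

Trait tables are CSV with header ``species,ctmin_c,ctmax_c,n,site``;
temperature logs are CSV with header ``timestamp,temp_c`` and ISO-8601
timestamps.  Simulation configurations round-trip through plain
JSON/YAML-compatible dictionaries mirroring the dataclass field names.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .environment import EnvironmentConfig, ProductivityModel
from .simulator import SimulationConfig
from .thermal_traits import TraitPrior

__all__ = [
    "TraitTableError",
    "read_trait_table",
    "write_trait_table",
    "read_temperature_log",
    "simulation_config_from_dict",
    "simulation_config_to_dict",
    "read_simulation_config",
    "write_manifest",
]

TRAIT_COLUMNS = ["species", "ctmin_c", "ctmax_c", "n", "site"]


class TraitTableError(ValueError):
    """Raised for malformed trait tables, with offending row numbers."""


def _validate_trait_table(df: pd.DataFrame, source: str = "trait table") -> pd.DataFrame:
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns and c != "site"]
    if missing:
        raise TraitTableError(f"{source}: missing column(s) {missing}")
    if "site" not in df.columns:
        df = df.assign(site="")
    for col in ("ctmin_c", "ctmax_c", "n"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise TraitTableError(f"{source}: non-numeric values in {col!r}: {exc}") from exc
    bad = df.index[~(df["ctmin_c"] < df["ctmax_c"])].tolist()
    if bad:
        raise TraitTableError(
            f"{source}: ctmin_c >= ctmax_c in row(s) {[int(b) + 2 for b in bad]} "
            "(row numbers include the header line)"
        )
    bad = df.index[df["n"] <= 0].tolist()
    if bad:
        raise TraitTableError(f"{source}: non-positive n in row(s) {[int(b) + 2 for b in bad]}")
    dup = df.duplicated(subset=["species", "site"])
    if dup.any():
        rows = df.index[dup].tolist()
        raise TraitTableError(
            f"{source}: duplicate species within a site in row(s) {[int(r) + 2 for r in rows]}"
        )
    return df[TRAIT_COLUMNS]


def read_trait_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a trait table CSV."""
    df = pd.read_csv(path)
    return _validate_trait_table(df, source=str(path))


def write_trait_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Validate and write a trait table CSV (full float precision)."""
    table = _validate_trait_table(table.reset_index(drop=True))
    table.to_csv(path, index=False)


def read_temperature_log(path: Union[str, Path]) -> pd.DataFrame:
    """Read a logger CSV (``timestamp,temp_c``); missing values rejected."""
    df = pd.read_csv(path)
    for col in ("timestamp", "temp_c"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df["temp_c"].isna().any() or df["timestamp"].isna().any():
        raise ValueError(f"{path}: missing values in temperature log")
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="raise")
    df["temp_c"] = pd.to_numeric(df["temp_c"], errors="raise")
    return df


def simulation_config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if isinstance(d.get("seed"), np.random.SeedSequence):
        ss = d["seed"]
        d["seed"] = {"entropy": ss.entropy, "spawn_key": list(ss.spawn_key)}
    return d


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    env = EnvironmentConfig(**d.pop("env", {}))
    prod = ProductivityModel(**d.pop("prod", {}))
    prior = TraitPrior(**d.pop("prior", {}))
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config key(s): {sorted(unknown)}")
    return SimulationConfig(env=env, prod=prod, prior=prior, **d)


def read_simulation_config(path: Union[str, Path]) -> SimulationConfig:
    """Load a simulation configuration from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return simulation_config_from_dict(data)


def write_manifest(path: Union[str, Path], cfg: SimulationConfig, seed: int,
                   inputs=None, outputs=None) -> dict:
    """Write a JSON run manifest sufficient to re-run bit-identically."""
    from . import __version__

    manifest = {
        "tool": "thermassembly",
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": simulation_config_to_dict(dataclasses.replace(cfg, seed=seed)),
        "inputs": list(map(str, inputs or [])),
        "outputs": list(map(str, outputs or [])),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
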