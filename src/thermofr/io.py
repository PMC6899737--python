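"""CSV readers/writers and pipeline configuration.

All artifacts are plain CSV/JSON/YAML.  Readers validate the declared
schema row by row and drop rows flagged ``excluded`` (logging the
count); temperatures cross the I/O boundary in degC.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("thermofr")

TRIAL_COLUMNS = ["dataset_id", "predator_present", "temperature_C", "n0",
                 "n_survivors", "duration_days", "excluded"]
RESPIROMETRY_COLUMNS = ["species", "temperature_C", "dry_mass_mg", "o2_umol_per_h"]
STREAM_COLUMNS = ["stream_id", "mean_temp_C", "prey_density", "predator_abundance"]


DEFAULT_CONFIG = {
    "seed": 0,
    "constants": {
        "boltzmann_eV_K": 8.618e-5,
        "T0_K": 283.15,
        "T0_star_K": 293.15,
    },
    "assimilation": {"log_omega0": 2.266, "E_omega_eV": 0.164},
    "prey": {"mass_mg": 0.546, "energy_J_per_mg": 23.1},
    "solver": {"rtol": 1e-8, "atol": 1e-10},
    "optimizer": {"n_starts": 10},
    "energetics": {
        "field_rate_multiplier": 1.0,
        "area_scaling": 1.0,
        "predator_mass_mg": 2.0,
    },
    "paths": {"trials": None, "respirometry": None, "streams": None},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Load a YAML config on top of the defaults (always a fresh copy)."""
    import copy

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    return cfg


def config_hash(config: dict) -> str:
    """Short stable hash identifying a run's configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def echo_config(config: dict, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return path


def constants_from_config(config: dict):
    from .constants import PhysicalConstants

    c = config["constants"]
    return PhysicalConstants(boltzmann_eV_K=c["boltzmann_eV_K"],
                             T0_K=c["T0_K"], T0_star_K=c["T0_star_K"])


def assimilation_from_config(config: dict):
    from .thermal import AssimilationParams

    a = config["assimilation"]
    return AssimilationParams(omega0=float(np.exp(a["log_omega0"])),
                              E_omega_eV=a["E_omega_eV"],
                              T0_star_K=config["constants"]["T0_star_K"])


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a feeding-trials CSV; excluded rows are dropped."""
    df = pd.read_csv(path)
    _require_columns(df, ["dataset_id", "predator_present", "temperature_C",
                          "n0", "n_survivors"], path)
    if "duration_days" not in df.columns:
        df["duration_days"] = 1.0
    if "excluded" not in df.columns:
        df["excluded"] = False
    for idx, row in df.iterrows():
        if row["n0"] < 0 or row["n_survivors"] < 0:
            raise ValueError(f"{path}: negative count in row {idx}")
        if row["n_survivors"] > row["n0"]:
            raise ValueError(
                f"{path}: n_survivors ({row['n_survivors']}) exceeds n0 "
                f"({row['n0']}) in row {idx}")
    n_excluded = int(df["excluded"].astype(bool).sum())
    if n_excluded:
        logger.info("dropping %d excluded arenas from %s", n_excluded, path)
    df = df[~df["excluded"].astype(bool)].reset_index(drop=True)
    df["predator_present"] = df["predator_present"].astype(bool)
    return df


def read_respirometry(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RESPIROMETRY_COLUMNS, path)
    bad = df.index[df["o2_umol_per_h"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative oxygen consumption in row {bad[0]}")
    return df


def read_streams(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, STREAM_COLUMNS, path)
    bad = df.index[(df["prey_density"] < 0) | (df["predator_abundance"] < 0)]
    if len(bad):
        raise ValueError(f"{path}: negative density in row {bad[0]}")
    return df


def write_table(df: pd.DataFrame, path, config: dict | None = None) -> Path:
    """Write a CSV artifact, stamping the config hash as a column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    if config is not None:
        out["config_hash"] = config_hash(config)
    out.to_csv(path, index=False)
    return path


def write_json(obj, path, config: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"config_hash": config_hash(config)} if config is not None else {}
    payload.update(obj if isinstance(obj, dict) else {"data": obj})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    return path
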