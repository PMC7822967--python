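"""Readers and writers for the package's on-disk formats.

All tabular data are plain CSV with 1-based pulse and repeat indices
(matching the P1-P20 nomenclature), times in ms and currents in pA
magnitudes.  Parameter sets and run metadata are JSON.  Readers validate
schemas and report missing or malformed columns by name; write/read
round-trips are lossless to full float precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .inference import FitDataset
from .model import StimulusProtocol, SynapseParams, TrainResponse
from .quantal import AmplitudeTable

__all__ = [
    "SchemaError",
    "write_amplitude_csv",
    "read_amplitude_csv",
    "write_recovery_csv",
    "read_recovery_csv",
    "save_params",
    "write_train_response_csv",
    "write_fit_dataset_csv",
    "read_fit_dataset_csv",
    "write_chains_csv",
    "read_config",
    "config_hash",
]

AMPLITUDE_COLUMNS = ["cell_id", "frequency_hz", "repeat", "pulse_index", "amplitude_pa"]
RECOVERY_COLUMNS = ["cell_id", "interval_ms", "repeat", "p1_pa", "p2_pa"]


class SchemaError(ValueError):
    """A CSV file does not match the expected schema."""


def _check_columns(df: pd.DataFrame, required: list, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _check_one_based(df: pd.DataFrame, columns: list, path) -> None:
    for col in columns:
        if (df[col] < 1).any():
            raise SchemaError(f"{path}: column {col!r} must be 1-based (found {int(df[col].min())})")


def write_amplitude_csv(path, tables: Mapping[float, AmplitudeTable]) -> None:
    rows = []
    for freq in sorted(tables):
        tab = tables[freq]
        for r in range(tab.n_repeats):
            for p in range(tab.n_pulses):
                val = tab.amplitudes[r, p]
                if np.isfinite(val):
                    rows.append((tab.cell_id, freq, r + 1, p + 1, repr(float(val))))
    pd.DataFrame(rows, columns=AMPLITUDE_COLUMNS).to_csv(path, index=False)


def read_amplitude_csv(path, cell_id: str | None = None) -> dict:
    """Read amplitude tables, returned as ``{frequency_hz: AmplitudeTable}``.

    Missing (repeat, pulse) cells become NaN entries that downstream
    statistics skip.  If the file holds several cells, ``cell_id`` selects
    one; with a single cell it may be omitted.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, AMPLITUDE_COLUMNS, path)
    _check_one_based(df, ["repeat", "pulse_index"], path)
    cells = df["cell_id"].unique()
    if cell_id is None:
        if len(cells) > 1:
            raise SchemaError(f"{path}: multiple cells {list(cells)}; pass cell_id")
        cell_id = cells[0]
    df = df[df["cell_id"] == cell_id]
    out = {}
    for freq, grp in df.groupby("frequency_hz"):
        n_rep = int(grp["repeat"].max())
        n_pul = int(grp["pulse_index"].max())
        amps = np.full((n_rep, n_pul), np.nan)
        amps[grp["repeat"] - 1, grp["pulse_index"] - 1] = grp["amplitude_pa"]
        out[float(freq)] = AmplitudeTable(
            amplitudes=amps, frequency_hz=float(freq), cell_id=str(cell_id)
        )
    return out


def write_recovery_csv(path, recovery: Mapping[float, np.ndarray], cell_id: str = "") -> None:
    rows = []
    for interval in sorted(recovery):
        pairs = np.atleast_2d(np.asarray(recovery[interval], dtype=float))
        for r in range(pairs.shape[0]):
            rows.append((cell_id, interval, r + 1, repr(float(pairs[r, 0])), repr(float(pairs[r, 1]))))
    pd.DataFrame(rows, columns=RECOVERY_COLUMNS).to_csv(path, index=False)


def read_recovery_csv(path, cell_id: str | None = None) -> dict:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, RECOVERY_COLUMNS, path)
    _check_one_based(df, ["repeat"], path)
    if cell_id is not None:
        df = df[df["cell_id"] == cell_id]
    out = {}
    for interval, grp in df.groupby("interval_ms"):
        grp = grp.sort_values("repeat")
        out[float(interval)] = grp[["p1_pa", "p2_pa"]].to_numpy(dtype=float)
    return out


def save_params(path, params: SynapseParams) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def write_train_response_csv(path, response: TrainResponse) -> None:
    response.to_frame().to_csv(path, index=False)


def write_fit_dataset_csv(path, dataset: FitDataset) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_fit_dataset_csv(path) -> FitDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["kind", "key", "pulse_index", "p_r"], path)
    return FitDataset.from_frame(df)


def write_chains_csv(path, chains: np.ndarray, param_names, sigma2: np.ndarray) -> None:
    df = pd.DataFrame(chains, columns=list(param_names))
    df["error_variance"] = sigma2
    df.to_csv(path, index=False)


def read_config(path) -> dict:
    """Flat ``key: value`` configuration file (YAML subset)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a flat key: value mapping")
    return cfg


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping, for run provenance."""
    blob = json.dumps({k: config[k] for k in sorted(config)}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
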