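"""Persistence for connectivity matrices, rasters and derived curves.

Connectivity travels as a sparse triplet text file (row, col, weight CSV)
with a JSON header carrying the model parameters and seed, or as a dense
``.npz`` container when speed matters.  Rasters are stored as an event
list CSV (neuron_id, t) with a JSON sidecar.  All text outputs are plain
CSV/JSON; pandas transparently gzips paths ending in ``.gz``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import SpikeRaster
from .network import ConnectivityMatrix
from .params import ModelParams, SimulationConfig

__all__ = [
    "save_connectivity",
    "load_connectivity",
    "save_connectivity_npz",
    "load_connectivity_npz",
    "save_raster",
    "load_raster",
    "save_rate_series",
]


def _params_dict(params: ModelParams) -> dict:
    return dataclasses.asdict(params)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_connectivity(conn: ConnectivityMatrix, path) -> Path:
    """Write J as (row, col, weight) triplets plus a JSON header."""
    path = Path(path)
    rows, cols = np.nonzero(conn.J)
    pd.DataFrame(
        {"row": rows, "col": cols, "weight": conn.J[rows, cols]}
    ).to_csv(path, index=False, float_format="%.17g")  # lossless roundtrip
    header = {
        "format": "critnet-connectivity-triplets",
        "N": conn.N,
        "seed": conn.seed,
        "params": _params_dict(conn.params),
    }
    _sidecar(path).write_text(json.dumps(header, indent=2))
    return path


def load_connectivity(path) -> ConnectivityMatrix:
    path = Path(path)
    header = json.loads(_sidecar(path).read_text())
    params = ModelParams(**header["params"])
    tab = pd.read_csv(path, float_precision="round_trip")
    J = np.zeros((params.N, params.N))
    J[tab["row"].to_numpy(), tab["col"].to_numpy()] = tab["weight"].to_numpy()
    n_exc = params.n_excitatory
    return ConnectivityMatrix(
        J=J,
        excitatory_ids=np.arange(n_exc),
        inhibitory_ids=np.arange(n_exc, params.N),
        params=params,
        seed=header.get("seed"),
    )


def save_connectivity_npz(conn: ConnectivityMatrix, path) -> Path:
    path = Path(path)
    np.savez_compressed(path, J=conn.J)
    header = {"seed": conn.seed, "params": _params_dict(conn.params)}
    _sidecar(path).write_text(json.dumps(header, indent=2))
    return path


def load_connectivity_npz(path) -> ConnectivityMatrix:
    path = Path(path)
    header = json.loads(_sidecar(path).read_text())
    params = ModelParams(**header["params"])
    J = np.load(path)["J"]
    n_exc = params.n_excitatory
    return ConnectivityMatrix(
        J=J,
        excitatory_ids=np.arange(n_exc),
        inhibitory_ids=np.arange(n_exc, params.N),
        params=params,
        seed=header.get("seed"),
    )


def save_raster(raster: SpikeRaster, path) -> Path:
    """Write the spike-event list (neuron_id, t) with a JSON sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"neuron_id": raster.event_ids, "t": raster.event_times}
    ).to_csv(path, index=False)
    meta = {
        "format": "critnet-raster-events",
        "N": raster.N,
        "T_steps": raster.T_steps,
        "burn_in": raster.burn_in,
        "seed": raster.seed,
        "params": _params_dict(raster.params) if raster.params else None,
        "config": dataclasses.asdict(raster.config) if raster.config else None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_raster(path) -> SpikeRaster:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    tab = pd.read_csv(path)
    times = tab["t"].to_numpy(np.int64)
    ids = tab["neuron_id"].to_numpy(np.int32)
    counts = np.bincount(times, minlength=meta["T_steps"]).astype(np.int64)
    return SpikeRaster(
        event_times=times,
        event_ids=ids,
        counts=counts,
        N=meta["N"],
        T_steps=meta["T_steps"],
        burn_in=meta["burn_in"],
        params=ModelParams(**meta["params"]) if meta.get("params") else None,
        config=SimulationConfig(**meta["config"]) if meta.get("config") else None,
        seed=meta.get("seed"),
    )


def save_rate_series(raster: SpikeRaster, path, exclude_burn_in: bool = True) -> Path:
    """Export S(t) as a two-column CSV (t, S)."""
    path = Path(path)
    t0 = raster.burn_in if exclude_burn_in else 0
    counts = raster.counts[t0:]
    pd.DataFrame(
        {"t": np.arange(t0, raster.T_steps), "S": counts / raster.N}
    ).to_csv(path, index=False)
    return path
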