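"""HDF5/CSV serialisation for connectomes, rasters, trajectories and histories."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .dynamics import TimeGrid
from .network import Connectome, MGCConfig, SimRecord
from .plasticity import WeightHistory
from .readout import TrajectorySet

__all__ = [
    "save_connectome",
    "load_connectome",
    "save_record",
    "load_record",
    "record_to_csv",
    "save_trajectories",
    "load_trajectories",
    "save_weight_history",
]

_PATHWAYS = ("w_orn_ln", "w_orn_pn", "w_ln_ln", "w_ln_pn", "w_pn_pn")
_MASKS = ("ln_ln_mask", "ln_pn_mask", "pn_pn_mask")


def save_connectome(conn: Connectome, path) -> None:
    """Pathway matrices as named HDF5 datasets; config as a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name in _PATHWAYS + _MASKS:
            f.create_dataset(name, data=getattr(conn, name))
        f.attrs["seed"] = conn.seed
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = dataclasses.asdict(conn.config)
    sidecar.write_text(json.dumps(cfg, indent=2))


def load_connectome(path) -> Connectome:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    raw = json.loads(sidecar.read_text())
    for key, val in raw.items():
        if isinstance(val, list):
            raw[key] = tuple(val)
    config = MGCConfig(**raw)
    with h5py.File(path, "r") as f:
        kwargs = {name: f[name][...] for name in _PATHWAYS}
        kwargs.update({name: f[name][...].astype(bool) for name in _MASKS})
        seed = int(f.attrs["seed"])
    return Connectome(config=config, seed=seed, **kwargs)


def save_record(record: SimRecord, path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("orn_spikes", "ln_spikes", "pn_spikes"):
            f.create_dataset(name, data=getattr(record, name))
        if record.v_traces is not None:
            f.create_dataset("v_traces", data=record.v_traces)
        f.attrs["delta"] = record.grid.delta
        f.attrs["n_steps"] = record.grid.n_steps


def load_record(path) -> SimRecord:
    with h5py.File(path, "r") as f:
        grid = TimeGrid(delta=float(f.attrs["delta"]), n_steps=int(f.attrs["n_steps"]))
        return SimRecord(
            grid=grid,
            orn_spikes=f["orn_spikes"][...].astype(bool),
            ln_spikes=f["ln_spikes"][...].astype(bool),
            pn_spikes=f["pn_spikes"][...].astype(bool),
            v_traces=f["v_traces"][...] if "v_traces" in f else None,
        )


def record_to_csv(record: SimRecord, path) -> None:
    """Two-column (neuron_id, spike_step) CSV, 0-based step indices."""
    record.spike_table().to_csv(path, index=False)


def save_trajectories(ts: TrajectorySet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("trajectories", data=ts.trajectories)
        f.create_dataset(
            "labels", data=np.array(ts.labels, dtype=h5py.string_dtype())
        )
        f.attrs["delta"] = ts.grid.delta
        f.attrs["n_steps"] = ts.grid.n_steps


def load_trajectories(path) -> TrajectorySet:
    with h5py.File(path, "r") as f:
        grid = TimeGrid(delta=float(f.attrs["delta"]), n_steps=int(f.attrs["n_steps"]))
        return TrajectorySet(
            trajectories=f["trajectories"][...],
            labels=[s.decode() if isinstance(s, bytes) else str(s)
                    for s in f["labels"][...]],
            grid=grid,
        )


def save_weight_history(history: WeightHistory, path, csv_path=None) -> None:
    """Epoch-indexed snapshots to HDF5; per-epoch change optionally to CSV."""
    with h5py.File(path, "w") as f:
        f.create_dataset("snapshot_epochs", data=np.asarray(history.snapshot_epochs))
        f.create_dataset("orn_ln", data=np.stack(history.orn_ln))
        f.create_dataset("ln_ln", data=np.stack(history.ln_ln))
        f.create_dataset("per_epoch_change", data=history.per_epoch_change)
        f.attrs["stability_epoch"] = (
            -1 if history.stability_epoch is None else history.stability_epoch
        )
        f.attrs["stability_epoch_relaxed"] = (
            -1
            if history.stability_epoch_relaxed is None
            else history.stability_epoch_relaxed
        )
        f.attrs["seed"] = history.seed
        f.attrs["epochs_run"] = history.epochs_run
    if csv_path is not None:
        history.change_dataframe().to_csv(csv_path, index=False)
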