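"""File formats: spike CSV, voltage traces (HDF5), results JSON helpers."""

from __future__ import annotations

import json
from typing import Dict, Iterable, Optional

import h5py
import numpy as np
import pandas as pd

from .simulator import SimulationResult

__all__ = [
    "spikes_to_frame",
    "write_spike_csv",
    "read_spike_csv",
    "write_voltage_h5",
    "read_voltage_h5",
    "write_results_json",
]


def spikes_to_frame(
    result: SimulationResult, populations: Optional[Iterable[str]] = None
) -> pd.DataFrame:
    """Flatten recorded spikes into a (neuron_id, time_ms) table.

    ``neuron_id`` is ``"<pop>:<index>"``; rows are sorted by time then id.
    """
    pops = list(populations) if populations is not None else list(result.spikes)
    ids, times = [], []
    for pid in pops:
        for i, train in enumerate(result.spikes[pid]):
            if train is None:
                continue
            ids.extend([f"{pid}:{i}"] * len(train))
            times.extend(train.tolist())
    frame = pd.DataFrame({"neuron_id": ids, "time_ms": times})
    return frame.sort_values(["time_ms", "neuron_id"], kind="stable").reset_index(
        drop=True
    )


def write_spike_csv(result: SimulationResult, path, populations=None) -> None:
    spikes_to_frame(result, populations).to_csv(path, index=False)


def read_spike_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_voltage_h5(result: SimulationResult, path) -> None:
    """Store voltage traces as one (neuron x timestep) dataset per population."""
    with h5py.File(path, "w") as fh:
        fh.attrs["dt"] = result.dt
        fh.attrs["duration"] = result.duration
        for pid, trace in result.voltages.items():
            fh.create_dataset(pid, data=trace)


def read_voltage_h5(path) -> Dict[str, np.ndarray]:
    out = {}
    with h5py.File(path, "r") as fh:
        for key in fh:
            out[key] = fh[key][...]
        out["__dt__"] = float(fh.attrs["dt"])
        out["__duration__"] = float(fh.attrs["duration"])
    return out


def write_results_json(path, payload: dict) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
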