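"""Disk formats: HDF5 trace matrices, CSV event logs and long-format traces,
JSON ground-truth sidecars."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd

from .core import EventLog, TraceMatrix
from .syngen import GroundTruth

PathLike = Union[str, Path]


def save_traces_h5(traces: TraceMatrix, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=traces.values)
        f.create_dataset("sample_rate", data=float(traces.sample_rate))
        f.create_dataset(
            "neuron_ids", data=np.array([s.encode() for s in traces.neuron_ids])
        )
        if traces.spikes is not None:
            f.create_dataset("spikes", data=traces.spikes)


def load_traces_h5(path: PathLike) -> TraceMatrix:
    with h5py.File(path, "r") as f:
        values = f["traces"][()]
        rate = float(f["sample_rate"][()])
        ids = [s.decode() for s in f["neuron_ids"][()]]
        spikes = f["spikes"][()] if "spikes" in f else None
    return TraceMatrix(values=values, sample_rate=rate, neuron_ids=ids, spikes=spikes)


def traces_to_long_csv(traces: TraceMatrix, path: PathLike) -> None:
    """Long format: neuron_id,time_s,value (one row per sample)."""
    t = traces.times
    frames = [
        pd.DataFrame({"neuron_id": nid, "time_s": t, "value": row})
        for nid, row in zip(traces.neuron_ids, traces.values)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_events_csv(events: EventLog, path: PathLike) -> None:
    events.events.to_csv(path, index=False)


def load_events_csv(path: PathLike) -> EventLog:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    df["solution"] = df.get("solution", "").fillna("")
    return EventLog(df)


def save_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    payload = {
        "neurons": truth.neurons.to_dict(orient="records"),
        "bout_truth": truth.bout_truth,
    }
    if truth.osmolality_curve is not None:
        # store the latent at 1 Hz to keep the sidecar small
        step = max(1, int(round(len(truth.osmolality_curve) / max(1, truth.osmolality_times_s[-1]))))
        payload["osmolality_times_s"] = list(np.asarray(truth.osmolality_times_s[::step], dtype=float))
        payload["osmolality_curve"] = list(np.asarray(truth.osmolality_curve[::step], dtype=float))
    with open(path, "w") as f:
        json.dump(payload, f, default=_json_default)


def load_ground_truth(path: PathLike) -> GroundTruth:
    with open(path) as f:
        payload = json.load(f)
    truth = GroundTruth(neurons=pd.DataFrame(payload["neurons"]))
    if payload.get("bout_truth") is not None:
        truth.bout_truth = [tuple(b) for b in payload["bout_truth"]]
    if "osmolality_curve" in payload:
        truth.osmolality_times_s = np.asarray(payload["osmolality_times_s"], dtype=float)
        truth.osmolality_curve = np.asarray(payload["osmolality_curve"], dtype=float)
    return truth


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_report(report: dict, path: PathLike) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=2, sort_keys=True, default=_json_default)
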