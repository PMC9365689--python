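"""Shared data containers for ingestion-phase analysis.

The containers are deliberately thin: a trace matrix is a float array plus a
sample rate and neuron ids, an event log is a tidy DataFrame of timestamped
behavioural events.  Heavier semantics (normalization state, epoch windows,
classification labels) live in the modules that create them.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

EVENT_KINDS = (
    "lick",
    "infusion_start",
    "infusion_stop",
    "injection",
    "access_start",
    "access_stop",
)


def substream(seed: int, *keys) -> np.random.Generator:
    """Derive an independent, reproducible RNG substream from ``seed`` and keys.

    Keys are hashed (SHA-256) into the seed sequence so that e.g. adding
    neurons to a simulated session never perturbs the draws of existing ones.
    """
    h = hashlib.sha256()
    for k in keys:
        h.update(str(k).encode())
        h.update(b"\x1f")
    digest = int.from_bytes(h.digest()[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, digest]))


@dataclass
class TraceMatrix:
    """Neurons x samples fluorescence at a fixed sample rate (arbitrary units).

    ``spikes`` optionally carries an inferred event-rate channel of the same
    shape; it is stored and round-tripped but not analysed further here.
    """

    values: np.ndarray
    sample_rate: float
    neuron_ids: Sequence[str]
    spikes: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (neurons x samples) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.neuron_ids = list(self.neuron_ids)
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError("neuron_ids length must match number of rows")
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise ValueError("neuron_ids must be unique")
        if self.spikes is not None:
            self.spikes = np.asarray(self.spikes, dtype=float)
            if self.spikes.shape != self.values.shape:
                raise ValueError("spikes must match values shape")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class PhotometrySignal:
    """Paired fluorescence channels: signal (~470 nm) and isosbestic reference (~405 nm)."""

    signal: np.ndarray
    reference: np.ndarray
    sample_rate: float

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.signal.shape != self.reference.shape or self.signal.ndim != 1:
            raise ValueError("signal and reference must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(self.signal)) and np.all(np.isfinite(self.reference))):
            raise ValueError("photometry channels must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.signal.size) / self.sample_rate


@dataclass
class AccelSignal:
    """3-axis head acceleration, conventionally sampled at 50 Hz."""

    axes: np.ndarray
    sample_rate: float = 50.0

    def __post_init__(self):
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.ndim != 2 or self.axes.shape[0] != 3:
            raise ValueError("axes must be a (3, samples) array")
        if not np.all(np.isfinite(self.axes)):
            raise ValueError("acceleration must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass
class EventLog:
    """Timestamped behavioural events (licks, infusions, injections, bottle access).

    Backed by a DataFrame with columns ``time_s, kind, solution, volume_ul``.
    Times are non-decreasing and every infusion_start has a later matching
    infusion_stop.
    """

    events: pd.DataFrame = field(default_factory=lambda: EventLog.empty_frame())

    @staticmethod
    def empty_frame() -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": pd.Series(dtype=float),
                "kind": pd.Series(dtype=str),
                "solution": pd.Series(dtype=str),
                "volume_ul": pd.Series(dtype=float),
            }
        )

    def __post_init__(self):
        df = pd.DataFrame(self.events)
        for col, default in (("solution", ""), ("volume_ul", np.nan)):
            if col not in df.columns:
                df[col] = default
        df = df[["time_s", "kind", "solution", "volume_ul"]].reset_index(drop=True)
        bad = set(df["kind"]) - set(EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds: {sorted(bad)}")
        if len(df) and np.any(np.diff(df["time_s"].to_numpy()) < 0):
            raise ValueError("event times must be non-decreasing")
        n_start = int((df["kind"] == "infusion_start").sum())
        n_stop = int((df["kind"] == "infusion_stop").sum())
        if n_start != n_stop:
            raise ValueError("every infusion_start needs a matching infusion_stop")
        self.events = df

    def times(self, kind: str) -> np.ndarray:
        return self.events.loc[self.events["kind"] == kind, "time_s"].to_numpy(dtype=float)

    def first(self, kind: str) -> Optional[float]:
        t = self.times(kind)
        return float(t[0]) if t.size else None

    def lick_times(self) -> np.ndarray:
        return self.times("lick")

    def __len__(self) -> int:
        return len(self.events)

    @staticmethod
    def from_records(records) -> "EventLog":
        """Build from an iterable of (time_s, kind[, solution[, volume_ul]]) tuples."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            time_s, kind = rec[0], rec[1]
            solution = rec[2] if len(rec) > 2 else ""
            volume = rec[3] if len(rec) > 3 else np.nan
            rows.append((float(time_s), kind, solution, volume))
        df = pd.DataFrame(rows, columns=["time_s", "kind", "solution", "volume_ul"])
        df = df.sort_values("time_s", kind="stable").reset_index(drop=True)
        return EventLog(df)

    @staticmethod
    def concat(logs: Sequence["EventLog"]) -> "EventLog":
        frames = [l.events for l in logs if len(l)]
        if not frames:
            return EventLog()
        df = pd.concat(frames, ignore_index=True).sort_values("time_s", kind="stable")
        return EventLog(df.reset_index(drop=True))
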