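"""Behavioural quantities: lick bouts, fluid preference, consumption,
movement/rest segmentation.

A *lick bout* is any maximal run of licks spanning at least ``min_duration``
seconds (first lick to last) in which no inter-lick interval exceeds
``max_gap`` seconds (defaults 10 s and 2 s).  The start of the first bout is
the session's oral anchor.

Movement detection follows the rectified-sum pipeline: |x|+|y|+|z| of head
acceleration, third-order zero-phase Butterworth lowpass at 5 Hz, then an
Otsu threshold on the filtered amplitude separates rest from movement.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import signal
from skimage.filters import threshold_otsu

from .core import AccelSignal, EventLog
from .syngen import TrainingDataset


@dataclass
class BoutSet:
    """Time-ordered, non-overlapping lick bouts: (start_s, end_s, lick_count)."""

    bouts: List[Tuple[float, float, int]]
    min_duration: float = 10.0
    max_gap: float = 2.0

    def __len__(self) -> int:
        return len(self.bouts)

    @property
    def first_bout_start(self) -> Optional[float]:
        return self.bouts[0][0] if self.bouts else None

    def total_licks(self) -> int:
        return sum(b[2] for b in self.bouts)


def detect_bouts(
    licks: Union[EventLog, np.ndarray],
    min_duration: float = 10.0,
    max_gap: float = 2.0,
) -> BoutSet:
    """Segment a lick train into bouts.

    Runs are maximal sets of consecutive licks with every inter-lick interval
    <= max_gap; runs whose span (last lick - first lick) >= min_duration are
    bouts.  A gap of exactly max_gap stays within a bout ("no interval
    greater than" the gap).
    """
    times = licks.lick_times() if isinstance(licks, EventLog) else np.asarray(licks, dtype=float)
    times = np.sort(times)
    if times.size == 0:
        return BoutSet([], min_duration, max_gap)
    breaks = np.flatnonzero(np.diff(times) > max_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [times.size - 1]])
    bouts = [
        (float(times[i0]), float(times[i1]), int(i1 - i0 + 1))
        for i0, i1 in zip(starts, ends)
        if times[i1] - times[i0] >= min_duration
    ]
    return BoutSet(bouts, min_duration, max_gap)


def preference_index(licks_target: int, licks_other: int) -> float:
    """Fraction of licks directed at the target solution: target/(target+other)."""
    total = licks_target + licks_other
    if total <= 0:
        raise ValueError("preference undefined: zero total licks")
    return licks_target / total


def two_bottle_preference(
    daily_counts: List[Tuple[int, int]],
) -> Tuple[float, List[float]]:
    """Pool a multi-day two-bottle test.

    Takes per-day (target, other) lick counts; returns the lick-weighted
    pooled preference (= total target / total licks) and per-day indices.
    """
    if not daily_counts:
        raise ValueError("no test days provided")
    per_day = [preference_index(t, o) for t, o in daily_counts]
    tot_t = sum(t for t, _ in daily_counts)
    tot_o = sum(o for _, o in daily_counts)
    return preference_index(tot_t, tot_o), per_day


def consumption_summary(training: TrainingDataset) -> pd.DataFrame:
    """Per-mouse per-day lick counts and infused volume per solution.

    On closed-loop training days the infused volume equals licks x 1 ul by
    construction; days with no licks report explicit zeros.
    """
    rows = []
    for d in training.days:
        ev = d.events.events
        lick_rows = ev[ev["kind"] == "lick"]
        inf_rows = ev[ev["kind"] == "infusion_start"]
        solutions = sorted(set(lick_rows["solution"])) or [d.solution or ""]
        for sol in solutions:
            n_licks = int((lick_rows["solution"] == sol).sum())
            rows.append(
                {
                    "mouse_id": d.mouse_id,
                    "day": d.day,
                    "phase": d.phase,
                    "solution": sol,
                    "licks": n_licks,
                    "infused_volume_ul": float(inf_rows["volume_ul"].sum()) if d.phase == "training" else 0.0,
                }
            )
    return pd.DataFrame(rows)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's between-class-variance-maximizing threshold on a 1-D sample
    (256 equal-width bins over the sample range)."""
    return float(threshold_otsu(np.asarray(values, dtype=float), nbins=nbins))


def movement_segments(
    accel: AccelSignal, cutoff_hz: float = 5.0, order: int = 3, nbins: int = 256
) -> Tuple[np.ndarray, float]:
    """Label each sample movement (True) or rest (False).

    Pipeline: rectified sum over axes -> zero-phase Butterworth lowpass at
    ``cutoff_hz`` -> Otsu threshold; samples at or below the threshold are
    rest.  A degenerate (constant) signal yields all-rest with a warning.
    """
    if accel.axes.shape[1] < 2 * accel.sample_rate:
        raise ValueError("need at least 2 s of accelerometer data")
    rect = np.abs(accel.axes).sum(axis=0)
    sos = signal.butter(order, cutoff_hz, btype="low", fs=accel.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rect)
    if np.ptp(filtered) == 0:
        warnings.warn("constant acceleration signal; labelling all samples rest", RuntimeWarning)
        return np.zeros(filtered.size, dtype=bool), float(filtered[0])
    thr = otsu_threshold(filtered, nbins=nbins)
    return filtered > thr, thr
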