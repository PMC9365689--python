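"""Epoch construction, response classification, and latency estimation.

Core inference for stage-resolved ingestion analysis:

* epochs anchored to behavioural events — oral: 30 s from the first lick
  bout; gastrointestinal: the first 12 min of intragastric infusion;
  systemic: 12–32 min (imaging) or 12–50 min (photometry) after the anchor;
  0–30 min after an intraperitoneal injection;
* per-neuron epoch mean z change and the ±1z activated/inhibited rule, with
  an exclusive variant requiring the epoch to dominate all others;
* population-weighted z-score: fraction of neurons in a response class times
  that class's mean z change;
* onset latency (t50) and persistence from a 4-parameter logistic fit of the
  post-anchor rise;
* cross-condition correlation of matched neuron responses with a
  pairing-permutation p-value, and cross-session neuron matching by optimal
  bipartite assignment of centroids.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .behavior import detect_bouts
from .core import EventLog, substream
from .normalize import DffTrace, ZTraceMatrix

EPOCH_LABELS = ("baseline", "oral", "gastrointestinal", "systemic", "ip_systemic", "post_ingestion")


@dataclass
class EpochSet:
    """Named analysis windows in session seconds, plus the anchor they hang on."""

    windows: Dict[str, Tuple[float, float]]
    anchor_s: float
    modality: str
    preset: str = "start_anchored"

    def __getitem__(self, label: str) -> Tuple[float, float]:
        return self.windows[label]

    def response_labels(self) -> List[str]:
        return [l for l in self.windows if l != "baseline"]


def define_epochs(
    events: EventLog,
    modality: str,
    manipulation: str,
    preset: str = "start_anchored",
    baseline_min: float = 10.0,
) -> EpochSet:
    """Build the stage windows for a session.

    start_anchored (default): systemic = 12–32 min (imaging) or 12–50 min
    (photometry) after the anchor (infusion start or first-bout start); GI =
    first 12 min of infusion; oral = 30 s from first-bout start; IP systemic
    = 0–30 min from injection.  legacy_end_anchored instead defines a
    post_ingestion window 0–20 min after consumption/infusion *ends* (0–30
    min for IP), the convention used before rise-time analysis motivated the
    start-anchored one.
    """
    if modality not in ("imaging", "photometry"):
        raise ValueError(f"unknown modality {modality!r}")
    if preset not in ("start_anchored", "legacy_end_anchored"):
        raise ValueError(f"unknown epoch preset {preset!r}")
    windows: Dict[str, Tuple[float, float]] = {}

    bouts = detect_bouts(events)
    first_bout = bouts.first_bout_start
    inf_start = events.first("infusion_start")
    inf_stop = events.first("infusion_stop")
    injection = events.first("injection")
    access_stop = events.first("access_stop")

    if manipulation == "ig_infusion":
        if inf_start is None:
            raise ValueError("missing anchor: no infusion_start event")
        anchor = inf_start
    elif manipulation == "ip_injection":
        if injection is None:
            raise ValueError("missing anchor: no injection event")
        anchor = injection
    elif manipulation == "drinking":
        if first_bout is None:
            raise ValueError("missing anchor: no lick bout found")
        anchor = first_bout
    else:
        raise ValueError(f"unknown manipulation {manipulation!r}")

    windows["baseline"] = (max(0.0, anchor - baseline_min * 60.0), anchor)
    if first_bout is not None:
        windows["oral"] = (first_bout, first_bout + 30.0)
    if inf_start is not None:
        windows["gastrointestinal"] = (inf_start, inf_start + 12 * 60.0)

    if manipulation == "ip_injection":
        windows["ip_systemic"] = (injection, injection + 30 * 60.0)
    elif preset == "start_anchored":
        end_min = 32.0 if modality == "imaging" else 50.0
        windows["systemic"] = (anchor + 12 * 60.0, anchor + end_min * 60.0)
    else:  # legacy_end_anchored: 0-20 min after the end of consumption/infusion
        end_event = inf_stop if inf_stop is not None else access_stop
        if end_event is None:
            raise ValueError("missing end event for legacy_end_anchored preset")
        windows["post_ingestion"] = (end_event, end_event + 20 * 60.0)

    return EpochSet(windows=windows, anchor_s=anchor, modality=modality, preset=preset)


def epoch_response(
    z: Union[ZTraceMatrix, DffTrace, np.ndarray],
    epoch: Tuple[float, float],
    sample_rate: Optional[float] = None,
) -> np.ndarray:
    """Mean of the normalized signal over the epoch's samples (per neuron)."""
    if isinstance(z, (ZTraceMatrix, DffTrace)):
        values = np.atleast_2d(z.values)
        rate = z.sample_rate
    else:
        values = np.atleast_2d(np.asarray(z, dtype=float))
        if sample_rate is None:
            raise ValueError("sample_rate required for raw arrays")
        rate = sample_rate
    start_s, end_s = epoch
    i0 = int(round(start_s * rate))
    i1 = int(round(end_s * rate))
    i0 = max(0, i0)
    i1 = min(values.shape[1], i1)
    if i1 <= i0:
        raise ValueError(f"epoch {epoch} has no samples in the recording")
    return np.nanmean(values[:, i0:i1], axis=1)


def classify_neuron(responses: Dict[str, float], mode: str = "simple") -> Dict[str, str]:
    """±1z response labels per epoch.

    simple: activated iff mean > +1, inhibited iff mean < -1, else none
    (strict inequalities — a mean of exactly ±1 is none).  exclusive:
    additionally the epoch's mean must strictly exceed (activated) or fall
    strictly below (inhibited) every other epoch's mean.
    """
    if mode not in ("simple", "exclusive"):
        raise ValueError(f"unknown classification mode {mode!r}")
    labels = {}
    items = {k: v for k, v in responses.items() if k != "baseline"}
    for label, mean in items.items():
        others = [v for k, v in items.items() if k != label]
        if mean > 1.0 and (mode == "simple" or all(mean > o for o in others)):
            labels[label] = "activated"
        elif mean < -1.0 and (mode == "simple" or all(mean < o for o in others)):
            labels[label] = "inhibited"
        else:
            labels[label] = "none"
    return labels


def classify_population(
    z: ZTraceMatrix, epochs: EpochSet, mode: str = "simple"
) -> pd.DataFrame:
    """ResponseTable: one row per neuron x epoch with the mean z change and label."""
    labels = epochs.response_labels()
    means = {lab: epoch_response(z, epochs[lab]) for lab in labels}
    rows = []
    for i, nid in enumerate(z.neuron_ids):
        per_neuron = {lab: float(means[lab][i]) for lab in labels}
        lab_map = classify_neuron(per_neuron, mode=mode)
        for lab in labels:
            rows.append(
                {
                    "neuron_id": nid,
                    "epoch": lab,
                    "mean_z_change": per_neuron[lab],
                    "label": lab_map[lab],
                    "mode": mode,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PopulationSummary:
    """Fractions of activated/inhibited neurons and the population-weighted
    z-score of each group (fraction x group mean z change)."""

    n_neurons: int
    fraction_activated: float
    fraction_inhibited: float
    weighted_z_activated: float
    weighted_z_inhibited: float


def population_summary(table: pd.DataFrame, epoch: Optional[str] = None) -> PopulationSummary:
    """Summarize one epoch of a ResponseTable.

    weighted_z = (n_group / n_total) * mean(mean_z_change over the group);
    zero when the group is empty.
    """
    df = table if epoch is None else table[table["epoch"] == epoch]
    if df.empty:
        raise ValueError("no neurons in table")
    n = df["neuron_id"].nunique()
    act = df[df["label"] == "activated"]
    inh = df[df["label"] == "inhibited"]
    fa = len(act) / n
    fi = len(inh) / n
    wa = fa * float(act["mean_z_change"].mean()) if len(act) else 0.0
    wi = fi * float(inh["mean_z_change"].mean()) if len(inh) else 0.0
    return PopulationSummary(n, fa, fi, wa, wi)


# ---------------------------------------------------------------------------
# rise-time / persistence
# ---------------------------------------------------------------------------

@dataclass
class RiseFit:
    floor: float
    amplitude: float
    t50_min: float
    slope_min: float
    persistence_min: Optional[float]
    persistence_censored: bool
    r2: float
    converged: bool
    direction: str


def _logistic(t, floor, amp, t50, slope):
    return floor + amp / (1.0 + np.exp(-(t - t50) / slope))


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, width)
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad : pad + x.size]


def fit_rise(
    trace: np.ndarray,
    sample_rate: float,
    anchor_s: float,
    direction: str = "activated",
    window_min: Tuple[float, float] = (0.0, 40.0),
    smooth_s: float = 30.0,
) -> RiseFit:
    """Onset latency and persistence of a delayed response.

    The post-anchor segment (``window_min`` minutes after the anchor) is
    analysed; inhibited traces are sign-flipped first.  A 4-parameter
    logistic (floor, amplitude, midpoint, slope) is least-squares fitted to
    the rising portion — anchor up to the peak of a ``smooth_s`` moving
    average — with a multi-start grid over midpoint (window quartiles) and
    slope.  t50 is the fitted midpoint in minutes after the anchor.
    Persistence is the duration the smoothed trace stays above 50% of its
    peak change (the contiguous run containing the peak); if that run is cut
    off by the end of the window it is reported censored.
    """
    if direction not in ("activated", "inhibited"):
        raise ValueError("direction must be 'activated' or 'inhibited'")
    if window_min[1] - window_min[0] < 4.0:
        raise ValueError("fitting window must span at least 4 minutes")
    x = np.asarray(trace, dtype=float)
    i0 = int(round((anchor_s + window_min[0] * 60.0) * sample_rate))
    i1 = min(x.size, int(round((anchor_s + window_min[1] * 60.0) * sample_rate)))
    seg = x[i0:i1]
    if seg.size < sample_rate * 240:
        raise ValueError("fewer than 4 minutes of samples after the anchor")
    if direction == "inhibited":
        seg = -seg
    t_min = np.arange(seg.size) / sample_rate / 60.0 + window_min[0]

    sm = _smooth(seg, int(round(smooth_s * sample_rate)))
    peak_idx = int(np.argmax(sm))
    peak_val = float(sm[peak_idx])
    fit_end = max(peak_idx + 1, int(sample_rate * 240))
    tf, yf = t_min[:fit_end], seg[:fit_end]

    span = tf[-1] - tf[0]
    amp0 = max(peak_val - float(sm[:fit_end].min()), 1e-3)
    best, best_sse = None, np.inf
    for q in (0.25, 0.5, 0.75):
        for s0 in (0.2, 1.0, 3.0):
            p0 = (float(sm[0]), amp0, tf[0] + q * span, s0)
            try:
                popt, _ = optimize.curve_fit(
                    _logistic, tf, yf, p0=p0,
                    bounds=(
                        [-np.inf, 0.0, tf[0], 0.02],
                        [np.inf, 10 * amp0 + 1, tf[-1], max(10.0, span)],
                    ),
                    maxfev=5000,
                )
            except RuntimeError:
                continue
            sse = float(np.sum((yf - _logistic(tf, *popt)) ** 2))
            if sse < best_sse:
                best, best_sse = popt, sse
    if best is None:
        return RiseFit(np.nan, np.nan, np.nan, np.nan, None, False, 0.0, False, direction)
    floor, amp, t50, slope = (float(v) for v in best)
    sst = float(np.sum((yf - yf.mean()) ** 2))
    r2 = 1.0 - best_sse / sst if sst > 0 else 0.0

    # persistence: contiguous run of the smoothed trace above half peak change
    half = floor + 0.5 * (peak_val - floor)
    above = sm >= half
    persistence = None
    censored = False
    if above[peak_idx]:
        lo = peak_idx
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = peak_idx
        while hi < above.size - 1 and above[hi + 1]:
            hi += 1
        persistence = (hi - lo + 1) / sample_rate / 60.0
        censored = hi == above.size - 1
    return RiseFit(floor, amp, t50, slope, persistence, censored, r2, True, direction)


# ---------------------------------------------------------------------------
# cross-condition correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r: float
    p_permutation: float
    exact: bool
    ci_x: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


def cross_condition_correlation(
    resp_a: Sequence[float],
    resp_b: Sequence[float],
    n_iter: int = 10000,
    seed: int = 0,
    exact_cap: int = 2**20,
) -> CorrelationResult:
    """Correlation of matched per-neuron responses across two conditions.

    Ordinary least-squares slope and Pearson r; two-sided p by permuting the
    pairing (exhaustive over all n! pairings when feasible, else Monte Carlo
    with the add-one rule); 95% t-based confidence band for the fitted line.
    """
    a = np.asarray(resp_a, dtype=float)
    b = np.asarray(resp_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need matched samples with n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: zero variance in a condition")
    n = a.size
    slope, intercept = np.polyfit(a, b, 1)
    r_obs = float(np.corrcoef(a, b)[0, 1])

    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    if math.factorial(n) <= exact_cap:
        perms = np.array(list(itertools.permutations(range(n))))
        null = (az[None, :] * bz[perms]).mean(axis=1)
        hits = int(np.sum(np.abs(null) >= abs(r_obs) - 1e-12))
        p = hits / len(perms)
        exact = True
    else:
        rng = substream(seed, "pairing-permutation")
        idx = np.argsort(rng.random((n_iter, n)), axis=1)
        null = (az[None, :] * bz[idx]).mean(axis=1)
        hits = int(np.sum(np.abs(null) >= abs(r_obs) - 1e-12))
        p = (hits + 1) / (n_iter + 1)
        exact = False

    # 95% CI of the regression line at a grid of x values
    resid = b - (slope * a + intercept)
    s2 = float(np.sum(resid**2)) / (n - 2) if n > 2 else 0.0
    sxx = float(np.sum((a - a.mean()) ** 2))
    xg = np.linspace(a.min(), a.max(), 50)
    se = np.sqrt(s2 * (1.0 / n + (xg - a.mean()) ** 2 / sxx))
    tcrit = sps.t.ppf(0.975, n - 2)
    yhat = slope * xg + intercept
    return CorrelationResult(
        slope=float(slope), intercept=float(intercept), r=r_obs,
        p_permutation=float(p), exact=exact,
        ci_x=xg, ci_low=yhat - tcrit * se, ci_high=yhat + tcrit * se,
    )


# ---------------------------------------------------------------------------
# cross-session neuron matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    pairs: List[Tuple[int, int]]  # (index in A, index in B)
    distances: List[float]
    unmatched_a: List[int]
    unmatched_b: List[int]

    def total_distance(self) -> float:
        return float(sum(self.distances))


def match_neurons(
    centroids_a: np.ndarray, centroids_b: np.ndarray, max_dist: float = 15.0
) -> MatchResult:
    """One-to-one partial matching of neuron centroids across sessions.

    Optimal bipartite assignment (Hungarian algorithm) that maximizes the
    number of pairs within ``max_dist`` (micrometres, roughly one soma
    diameter by default) and, among those, minimizes total distance.  All
    matches are returned for downstream manual verification.
    """
    A = np.atleast_2d(np.asarray(centroids_a, dtype=float))
    B = np.atleast_2d(np.asarray(centroids_b, dtype=float))
    if A.size == 0 or B.size == 0:
        na, nb = (A.shape[0] if A.size else 0), (B.shape[0] if B.size else 0)
        return MatchResult([], [], list(range(na)), list(range(nb)))
    dist = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    big = max_dist * (min(A.shape[0], B.shape[0]) + 1) + 1.0
    cost = np.where(dist <= max_dist, dist, big)
    rows, cols = optimize.linear_sum_assignment(cost)
    pairs, dists = [], []
    for i, j in zip(rows, cols):
        if dist[i, j] <= max_dist:
            pairs.append((int(i), int(j)))
            dists.append(float(dist[i, j]))
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    return MatchResult(
        pairs=pairs,
        distances=dists,
        unmatched_a=[i for i in range(A.shape[0]) if i not in matched_a],
        unmatched_b=[j for j in range(B.shape[0]) if j not in matched_b],
    )
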