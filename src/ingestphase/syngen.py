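"""Seeded synthetic sessions with ground truth.

Generates everything a desk-scale run of the analysis needs: bout-structured
lick trains, neuron populations with known response archetypes, calcium trace
matrices, dual-channel photometry with a shared motion artifact, 3-axis
accelerometer streams, and closed-loop flavour-training cohorts.  Every draw
comes from a keyed substream of one seed (see :func:`ingestphase.core.substream`)
so outputs are bit-identical under a fixed seed and adding neurons never
perturbs existing ones.

The response model
------------------
Each neuron belongs to one archetype:

* ``oral`` — calcium transients time-locked to licking (an exponential
  rise/decay kernel convolved with the lick train);
* ``gi`` — tonic elevation while fluid is being infused into the stomach,
  decaying shortly after the pump stops;
* ``systemic_activated`` / ``systemic_inhibited`` — a delayed sigmoidal ramp
  whose midpoint (the onset, default 14 min after infusion start or 10.1 min
  after drinking starts) and half-peak duration (persistence, default 30 min)
  track a latent blood-osmolality variable;
* ``none`` — noise only.

Systemic waveform: the product of a rising and a falling logistic,
``w(t) = sigm((t - t_on)/s) * sigm(-(t - t_on - persistence)/s)``,
so the time of half-peak rise equals the onset and the time spent above half
peak equals the persistence, by construction.  The session-level osmolality
latent has the same shape, scaled by infused volume and signed by tonicity
(negative deviation for water, positive for hypertonic saline); systemic
responders' drive is an affine map of it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import AccelSignal, EventLog, PhotometrySignal, TraceMatrix, substream

ARCHETYPES = ("oral", "gi", "systemic_activated", "systemic_inhibited", "none")


# ---------------------------------------------------------------------------
# designs and parameter bundles
# ---------------------------------------------------------------------------

@dataclass
class SessionDesign:
    """Shape of one recording session.

    duration/baseline in minutes; imaging defaults to 8 Hz, photometry to the
    acquisition-typical ~1017 Hz (analysis downsamples to 4 Hz).
    """

    modality: str = "imaging"  # imaging | photometry
    duration_min: float = 70.0
    sample_rate: Optional[float] = None
    baseline_min: float = 10.0
    manipulation: str = "ig_infusion"  # drinking | ig_infusion | ip_injection | closed_loop_training
    infusion_rate_ul_min: Optional[float] = 100.0
    infusion_volume_ul: Optional[float] = 1200.0
    solution: str = "water"
    seed: int = 0

    def __post_init__(self):
        if self.modality not in ("imaging", "photometry"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.manipulation not in (
            "drinking",
            "ig_infusion",
            "ip_injection",
            "closed_loop_training",
        ):
            raise ValueError(f"unknown manipulation {self.manipulation!r}")
        if self.sample_rate is None:
            self.sample_rate = 8.0 if self.modality == "imaging" else 1017.0
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.duration_min <= self.baseline_min:
            raise ValueError("duration must exceed the baseline period")
        needs_infusion = self.manipulation in ("ig_infusion", "closed_loop_training")
        has_infusion = self.infusion_rate_ul_min is not None and self.infusion_volume_ul is not None
        if needs_infusion and not has_infusion:
            raise ValueError("infusion rate and volume required for infusion manipulations")
        if not needs_infusion:
            self.infusion_rate_ul_min = None
            self.infusion_volume_ul = None

    @property
    def duration_s(self) -> float:
        return self.duration_min * 60.0

    @property
    def baseline_s(self) -> float:
        return self.baseline_min * 60.0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate))

    def infusion_duration_min(self) -> Optional[float]:
        if self.infusion_rate_ul_min is None:
            return None
        return self.infusion_volume_ul / self.infusion_rate_ul_min


@dataclass
class LickBoutParams:
    """Bout-structured lick train: bouts separated by gaps strictly > max_gap.

    Within-bout inter-lick intervals are drawn from [ili_min, ili_max] with
    ili_max <= 2 s, and inter-bout gaps from gap_min + Exp(gap_scale) with
    gap_min > 2 s, so the generator knows its own bout boundaries under the
    standard bout definition (span >= 10 s, every gap <= 2 s).
    """

    access_start_s: float = 600.0
    access_duration_s: float = 300.0
    bout_rate_per_min: float = 2.0
    bout_duration_mean_s: float = 20.0
    bout_duration_sd_s: float = 6.0
    bout_duration_min_s: float = 3.0
    ili_min_s: float = 0.10
    ili_max_s: float = 0.20
    gap_min_s: float = 3.0
    gap_scale_s: float = 15.0

    def __post_init__(self):
        if self.bout_rate_per_min < 0:
            raise ValueError("bout rate must be >= 0")
        if not (0 < self.ili_min_s <= self.ili_max_s <= 2.0):
            raise ValueError("inter-lick intervals must lie in (0, 2] s")
        if self.gap_min_s <= 2.0:
            raise ValueError("inter-bout gap floor must exceed the 2 s bout gap")


@dataclass
class EffectParams:
    """Amplitudes and systemic timing of the injected responses (z-units / minutes)."""

    peak_z_mean: float = 4.0
    peak_z_sd: float = 0.5
    onset_mean_min: float = 14.0
    onset_sd_min: float = 1.0
    persistence_mean_min: float = 30.0
    persistence_sd_min: float = 2.0
    sigmoid_spread_min: float = 0.5


def default_effects(manipulation: str) -> EffectParams:
    """Study-condition systemic timing: onset 14 min for intragastric infusion,
    10.1 min for self-paced drinking, 5 min for IP injection; persistence 30 min."""
    onset = {"ig_infusion": 14.0, "drinking": 10.1, "ip_injection": 5.0}.get(manipulation, 14.0)
    return EffectParams(onset_mean_min=onset)


@dataclass
class TraceNoise:
    """Raw-fluorescence noise model: white noise around a baseline offset, an
    optional slow drift, and a labelled fraction of bleaching neurons carrying
    an additive decaying exponential."""

    baseline_offset: float = 100.0
    noise_sd: float = 5.0
    drift_sd: float = 0.0
    bleach_fraction: float = 0.0
    bleach_amplitude_sds: float = 10.0
    bleach_tau_s: float = 180.0
    transient_rise_s: float = 0.2
    transient_decay_s: float = 1.5


@dataclass
class GroundTruth:
    """Per-neuron archetype/onset/amplitude record plus the session's
    osmolality latent; the oracle for recovery testing."""

    neurons: pd.DataFrame  # neuron_id, archetype, onset_min, peak_amplitude, persistence_min, bleach
    osmolality_times_s: Optional[np.ndarray] = None
    osmolality_curve: Optional[np.ndarray] = None
    bout_truth: Optional[List[Tuple[float, float, int]]] = None

    def archetype_counts(self) -> Dict[str, int]:
        counts = self.neurons["archetype"].value_counts().to_dict()
        return {a: int(counts.get(a, 0)) for a in ARCHETYPES}

    def ids_of(self, archetype: str) -> List[str]:
        m = self.neurons["archetype"] == archetype
        return list(self.neurons.loc[m, "neuron_id"])


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def gen_lick_train(
    design: SessionDesign,
    bout_params: Optional[LickBoutParams] = None,
    seed: Optional[int] = None,
) -> Tuple[EventLog, List[Tuple[float, float, int]]]:
    """Simulate a bout-structured lick train inside the access window.

    Returns the event log (access_start, licks, access_stop) together with the
    ground-truth bout boundaries ``(start_s, end_s, lick_count)`` — the runs
    whose span is >= 10 s, which is what bout detection should recover.
    """
    bp = bout_params or LickBoutParams()
    seed = design.seed if seed is None else seed
    if bp.access_start_s < 0 or bp.access_start_s + bp.access_duration_s > design.duration_s:
        raise ValueError("access window must lie inside the session")
    rng = substream(seed, "licks")
    access_end = bp.access_start_s + bp.access_duration_s

    licks: List[float] = []
    truth: List[Tuple[float, float, int]] = []
    t = bp.access_start_s
    if bp.bout_rate_per_min > 0:
        # First bout starts shortly after access; subsequent bouts follow
        # exponential inter-bout gaps bounded below by gap_min.
        t = bp.access_start_s + rng.exponential(5.0)
        while t < access_end:
            dur = rng.normal(bp.bout_duration_mean_s, bp.bout_duration_sd_s)
            dur = max(bp.bout_duration_min_s, dur)
            bout_licks = [t]
            while bout_licks[-1] - t < dur:
                nxt = bout_licks[-1] + rng.uniform(bp.ili_min_s, bp.ili_max_s)
                if nxt > access_end:
                    break
                bout_licks.append(nxt)
            if len(bout_licks) > 1:
                licks.extend(bout_licks)
                span = bout_licks[-1] - bout_licks[0]
                if span >= 10.0:
                    truth.append((bout_licks[0], bout_licks[-1], len(bout_licks)))
            t = bout_licks[-1] + bp.gap_min_s + rng.exponential(bp.gap_scale_s)

    records = [(bp.access_start_s, "access_start", design.solution, np.nan)]
    records += [(lt, "lick", design.solution, np.nan) for lt in licks]
    records.append((access_end, "access_stop", design.solution, np.nan))
    return EventLog.from_records(records), truth


def gen_events(
    design: SessionDesign,
    bout_params: Optional[LickBoutParams] = None,
) -> Tuple[EventLog, Optional[List[Tuple[float, float, int]]]]:
    """Build the manipulation-appropriate event stream for a session.

    The manipulation anchor (infusion start, injection, bottle access) is
    placed at the end of the baseline period.
    """
    anchor = design.baseline_s
    if design.manipulation == "drinking":
        bp = bout_params or LickBoutParams(access_start_s=anchor)
        return gen_lick_train(design, bp)
    if design.manipulation == "ig_infusion":
        stop = anchor + design.infusion_duration_min() * 60.0
        if stop > design.duration_s:
            raise ValueError("infusion extends past end of session")
        log = EventLog.from_records(
            [
                (anchor, "infusion_start", design.solution, design.infusion_volume_ul),
                (stop, "infusion_stop", design.solution, design.infusion_volume_ul),
            ]
        )
        return log, None
    if design.manipulation == "ip_injection":
        log = EventLog.from_records([(anchor, "injection", design.solution, np.nan)])
        return log, None
    raise ValueError("closed_loop_training sessions are built by gen_training_cohort")


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def largest_remainder_counts(n: int, fractions: Dict[str, float]) -> Dict[str, int]:
    """Integer archetype counts by the largest-remainder rule; ties broken by
    archetype declaration order; remainder mass goes to ``none``."""
    fr = {a: float(fractions.get(a, 0.0)) for a in ARCHETYPES if a != "none"}
    if any(v < 0 for v in fr.values()):
        raise ValueError("fractions must be non-negative")
    total = sum(fr.values())
    if total > 1.0 + 1e-9:
        raise ValueError("fractions must sum to <= 1")
    quotas = {a: n * v for a, v in fr.items()}
    counts = {a: int(math.floor(q)) for a, q in quotas.items()}
    short = int(round(n * total)) - sum(counts.values())
    order = sorted(fr, key=lambda a: (-(quotas[a] - counts[a]), ARCHETYPES.index(a)))
    for a in order[:short]:
        counts[a] += 1
    counts["none"] = n - sum(counts.values())
    return counts


def gen_population(
    n_neurons: int,
    fractions: Dict[str, float],
    effect: Optional[EffectParams] = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw a neuron population: archetypes per the largest-remainder rule,
    onsets/amplitudes/persistences from truncated normals."""
    eff = effect or EffectParams()
    counts = largest_remainder_counts(n_neurons, fractions)
    labels: List[str] = []
    for a in ARCHETYPES:
        labels.extend([a] * counts[a])
    order = substream(seed, "population", "shuffle").permutation(n_neurons)
    labels = [labels[i] for i in order]

    rows = []
    for i, arch in enumerate(labels):
        rng = substream(seed, "neuron", i)
        amp = max(0.5, rng.normal(eff.peak_z_mean, eff.peak_z_sd))
        onset = np.nan
        persistence = np.nan
        if arch.startswith("systemic"):
            onset = max(2.0, rng.normal(eff.onset_mean_min, eff.onset_sd_min))
            persistence = max(5.0, rng.normal(eff.persistence_mean_min, eff.persistence_sd_min))
        rows.append(
            {
                "neuron_id": f"n{i:04d}",
                "archetype": arch,
                "onset_min": onset,
                "peak_amplitude": amp,
                "persistence_min": persistence,
                "bleach": False,
            }
        )
    return GroundTruth(neurons=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def systemic_waveform(
    t_s: np.ndarray,
    anchor_s: float,
    onset_min: float,
    persistence_min: float,
    spread_min: float = 0.5,
) -> np.ndarray:
    """Unit-peak delayed ramp: rising logistic (midpoint = onset) times a
    falling logistic (midpoint = onset + persistence), in minutes post-anchor."""
    tm = (t_s - anchor_s) / 60.0
    rise = 1.0 / (1.0 + np.exp(-(tm - onset_min) / spread_min))
    fall = 1.0 / (1.0 + np.exp((tm - onset_min - persistence_min) / spread_min))
    return rise * fall


def _gi_waveform(t_s: np.ndarray, start_s: float, stop_s: float, tau_s: float = 30.0) -> np.ndarray:
    """Ramp to plateau over the infusion window, exponential decay after stop."""
    w = np.zeros_like(t_s)
    ramp = np.clip((t_s - start_s) / tau_s, 0.0, 1.0)
    during = (t_s >= start_s) & (t_s < stop_s)
    w[during] = ramp[during]
    after = t_s >= stop_s
    w[after] = np.exp(-(t_s[after] - stop_s) / tau_s)
    return w


def _transient_kernel(sample_rate: float, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials calcium transient kernel, peak-normalized."""
    if sample_rate < 2.0 / rise_s and sample_rate < 2.0 / decay_s:
        raise ValueError("sample rate too low to resolve the requested transient kinetics")
    n = int(math.ceil(6 * decay_s * sample_rate))
    t = np.arange(n) / sample_rate
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate transient kernel; check time constants")
    return k / peak


def _oral_waveform(
    t_s: np.ndarray, lick_times: np.ndarray, sample_rate: float, rise_s: float, decay_s: float
) -> np.ndarray:
    """Lick-locked transient train, normalized to unit peak over the session."""
    if lick_times.size == 0:
        return np.zeros_like(t_s)
    train = np.zeros(t_s.size)
    idx = np.round(lick_times * sample_rate).astype(int)
    idx = idx[(idx >= 0) & (idx < t_s.size)]
    np.add.at(train, idx, 1.0)
    kernel = _transient_kernel(sample_rate, rise_s, decay_s)
    w = np.convolve(train, kernel)[: t_s.size]
    peak = w.max()
    return w / peak if peak > 0 else w


def osmolality_latent(
    design: SessionDesign,
    anchor_s: float,
    t_s: np.ndarray,
    onset_min: float,
    persistence_min: float,
    spread_min: float = 0.5,
) -> np.ndarray:
    """Latent blood-osmolality deviation (arbitrary mOsm-like units), scaled by
    infused volume; negative (falling osmolality) for water, positive for
    hypertonic saline."""
    volume = design.infusion_volume_ul or 1200.0
    scale = 10.0 * volume / 1200.0
    sign = 1.0 if "nacl" in design.solution.lower() or "saline" in design.solution.lower() else -1.0
    return sign * scale * systemic_waveform(t_s, anchor_s, onset_min, persistence_min, spread_min)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def _anchor_time(design: SessionDesign, events: EventLog, bout_truth=None) -> float:
    if design.manipulation == "ig_infusion":
        t = events.first("infusion_start")
    elif design.manipulation == "ip_injection":
        t = events.first("injection")
    else:
        t = bout_truth[0][0] if bout_truth else events.first("lick")
    if t is None:
        raise ValueError(f"no anchor event found for manipulation {design.manipulation!r}")
    return t


def gen_traces(
    truth: GroundTruth,
    events: EventLog,
    design: SessionDesign,
    noise: Optional[TraceNoise] = None,
    seed: Optional[int] = None,
    effect: Optional[EffectParams] = None,
) -> TraceMatrix:
    """Render raw fluorescence traces for a population.

    Raw trace = offset + noise_sd * (white noise + amplitude * waveform)
    [+ bleach exponential for labelled bleach neurons], so that after baseline
    z-scoring the injected response has peak ~``peak_amplitude`` z-units.
    The baseline segment is stationary for non-bleach neurons.
    """
    nz = noise or TraceNoise()
    eff = effect or default_effects(design.manipulation)
    seed = design.seed if seed is None else seed
    n = len(truth.neurons)
    t_s = np.arange(design.n_samples) / design.sample_rate
    anchor = _anchor_time(design, events, truth.bout_truth)
    lick_times = events.lick_times()
    inf_start = events.first("infusion_start")
    inf_stop = events.first("infusion_stop")

    gi_wave = (
        _gi_waveform(t_s, inf_start, inf_stop) if inf_start is not None else np.zeros_like(t_s)
    )
    oral_wave = _oral_waveform(
        t_s, lick_times, design.sample_rate, nz.transient_rise_s, nz.transient_decay_s
    )

    # mark bleach neurons deterministically from the seed
    bleach_flags = np.zeros(n, dtype=bool)
    if nz.bleach_fraction > 0:
        n_bleach = int(round(nz.bleach_fraction * n))
        picks = substream(seed, "bleach", "select").choice(n, size=n_bleach, replace=False)
        bleach_flags[picks] = True
    truth.neurons["bleach"] = bleach_flags

    values = np.empty((n, t_s.size))
    for i, row in enumerate(truth.neurons.itertuples(index=False)):
        rng = substream(seed, "trace", i)
        eps = rng.standard_normal(t_s.size) if nz.noise_sd > 0 else np.zeros(t_s.size)
        if nz.drift_sd > 0:
            drift = np.cumsum(rng.normal(0, nz.drift_sd / math.sqrt(design.sample_rate), t_s.size))
            eps = eps + drift
        arch = row.archetype
        if arch == "oral":
            wave = oral_wave
        elif arch == "gi":
            wave = gi_wave
        elif arch == "systemic_activated":
            wave = systemic_waveform(
                t_s, anchor, row.onset_min, row.persistence_min, eff.sigmoid_spread_min
            )
        elif arch == "systemic_inhibited":
            wave = -systemic_waveform(
                t_s, anchor, row.onset_min, row.persistence_min, eff.sigmoid_spread_min
            )
        else:
            wave = 0.0
        trace = nz.baseline_offset + nz.noise_sd * (eps + row.peak_amplitude * np.asarray(wave))
        if row.bleach:
            trace = trace + nz.bleach_amplitude_sds * nz.noise_sd * np.exp(-t_s / nz.bleach_tau_s)
        values[i] = trace

    ids = list(truth.neurons["neuron_id"])
    truth.osmolality_times_s = t_s
    truth.osmolality_curve = osmolality_latent(
        design, anchor, t_s, eff.onset_mean_min, eff.persistence_mean_min
    )
    return TraceMatrix(values=values, sample_rate=design.sample_rate, neuron_ids=ids)


def gen_session(
    design: SessionDesign,
    fractions: Optional[Dict[str, float]] = None,
    effect: Optional[EffectParams] = None,
    noise: Optional[TraceNoise] = None,
    bout_params: Optional[LickBoutParams] = None,
    n_neurons: int = 200,
) -> Tuple[TraceMatrix, EventLog, GroundTruth]:
    """One-call imaging session: events + population + traces, all from design.seed.

    Default archetype mixture mirrors the reported water-session percentages:
    22% oral, 39% systemic-activated, plus 10% GI and 5% systemic-inhibited.
    """
    fractions = fractions or {
        "oral": 0.22,
        "gi": 0.10,
        "systemic_activated": 0.39,
        "systemic_inhibited": 0.05,
    }
    effect = effect or default_effects(design.manipulation)
    events, bout_truth = gen_events(design, bout_params)
    truth = gen_population(n_neurons, fractions, effect, seed=design.seed)
    truth.bout_truth = bout_truth
    traces = gen_traces(truth, events, design, noise, seed=design.seed, effect=effect)
    return traces, events, truth


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

@dataclass
class RegionProfile:
    """Stage weights of a recording site's dopamine response (ΔF/F peak fractions)."""

    oral: float = 0.0
    gi: float = 0.0
    systemic: float = 0.0

    def __post_init__(self):
        for v in (self.oral, self.gi, self.systemic):
            if not np.isfinite(v):
                raise ValueError("region weights must be finite")


@dataclass
class ArtifactParams:
    """Shared motion artifact: a low-frequency random walk added to both
    channels with channel-specific gains."""

    walk_sd: float = 1.0
    signal_gain: float = 1.0
    reference_gain: float = 0.6
    smooth_s: float = 0.25
    channel_noise_sd: float = 0.02


def gen_photometry(
    region_profile: RegionProfile,
    events: EventLog,
    design: SessionDesign,
    artifact: Optional[ArtifactParams] = None,
    seed: Optional[int] = None,
    effect: Optional[EffectParams] = None,
) -> PhotometrySignal:
    """Dual-channel photometry: signal = baseline * (1 + stage-weighted
    response) + shared artifact; reference = baseline' + scaled same artifact."""
    art = artifact or ArtifactParams()
    eff = effect or default_effects(design.manipulation)
    seed = design.seed if seed is None else seed
    t_s = np.arange(design.n_samples) / design.sample_rate
    anchor = _anchor_time(design, events)

    inf_start = events.first("infusion_start")
    inf_stop = events.first("infusion_stop")
    gi_wave = (
        _gi_waveform(t_s, inf_start, inf_stop) if inf_start is not None else np.zeros_like(t_s)
    )
    lick_times = events.lick_times()
    oral_wave = (
        _oral_waveform(t_s, lick_times, design.sample_rate, 0.2, 1.5)
        if lick_times.size
        else np.zeros_like(t_s)
    )
    sys_wave = systemic_waveform(
        t_s, anchor, eff.onset_mean_min, eff.persistence_mean_min, eff.sigmoid_spread_min
    )
    response = (
        region_profile.oral * oral_wave
        + region_profile.gi * gi_wave
        + region_profile.systemic * sys_wave
    )

    rng = substream(seed, "photometry")
    if art.walk_sd > 0:
        walk = np.cumsum(rng.normal(0, art.walk_sd / math.sqrt(design.sample_rate), t_s.size))
        win = max(1, int(round(art.smooth_s * design.sample_rate)))
        kernel = np.ones(win) / win
        shared = np.convolve(walk, kernel, mode="same")
    else:
        shared = np.zeros(t_s.size)

    base_signal, base_reference = 200.0, 100.0
    signal = (
        base_signal * (1.0 + response)
        + art.signal_gain * shared
        + rng.normal(0, art.channel_noise_sd, t_s.size)
    )
    reference = (
        base_reference
        + art.reference_gain * shared
        + rng.normal(0, art.channel_noise_sd, t_s.size)
    )
    return PhotometrySignal(signal=signal, reference=reference, sample_rate=design.sample_rate)


# ---------------------------------------------------------------------------
# accelerometer
# ---------------------------------------------------------------------------

def gen_accelerometer(
    movement_bouts: Sequence[Tuple[float, float]],
    duration_s: float,
    noise_floor: float = 0.05,
    movement_sd: float = 1.0,
    sample_rate: float = 50.0,
    seed: int = 0,
) -> AccelSignal:
    """3-axis acceleration: Gaussian noise at the floor level at rest, higher
    variance inside the scheduled movement bouts."""
    for s, e in movement_bouts:
        if s < 0 or e > duration_s or e <= s:
            raise ValueError("movement bouts must lie inside the session")
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    moving = np.zeros(n, dtype=bool)
    for s, e in movement_bouts:
        moving |= (t >= s) & (t < e)
    rng = substream(seed, "accel")
    axes = rng.normal(0, noise_floor, size=(3, n))
    axes[:, moving] = rng.normal(0, movement_sd, size=(3, int(moving.sum())))
    return AccelSignal(axes=axes, sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# closed-loop flavour training
# ---------------------------------------------------------------------------

TRAINING_GROUPS = {
    1: {"grape": "nacl_600mM", "lime": "water", "order": ("grape", "lime")},
    2: {"grape": "nacl_600mM", "lime": "water", "order": ("lime", "grape")},
    3: {"grape": "water", "lime": "nacl_600mM", "order": ("grape", "lime")},
    4: {"grape": "water", "lime": "nacl_600mM", "order": ("lime", "grape")},
}


@dataclass
class LearningModel:
    """Drift of preference toward the water-paired flavour over training.

    Post-training preference (for the water-paired flavour) is
    clip(pre + n_training_days * daily_drift + noise, 0, 1); daily training
    consumption scales linearly with the current preference.
    """

    initial_pref_mean: float = 0.5
    initial_pref_sd: float = 0.05
    daily_drift: float = 0.06
    drift_sd: float = 0.0
    licks_per_session: float = 1000.0
    consumption_gain: float = 1.0

    def expected_change(self, n_training_days: int = 6) -> float:
        """Closed-form expected post-minus-pre preference change (ignoring the
        [0,1] clip, valid while drift keeps preferences interior)."""
        return self.daily_drift * n_training_days


@dataclass
class MouseDay:
    mouse_id: str
    day: int
    phase: str  # two_bottle_pre | training | two_bottle_post
    solution: Optional[str]  # training solution flavour, None on test days
    events: EventLog
    side_of_flavour: Optional[Dict[str, str]] = None  # two-bottle bottle sides


@dataclass
class TrainingDataset:
    """Per-mouse per-day event logs for a closed-loop flavour-training cohort."""

    mice: pd.DataFrame  # mouse_id, group, water_flavour, true_pre_pref, true_post_pref
    days: List[MouseDay] = field(default_factory=list)

    def days_of(self, mouse_id: str, phase: Optional[str] = None) -> List[MouseDay]:
        out = [d for d in self.days if d.mouse_id == mouse_id]
        if phase is not None:
            out = [d for d in out if d.phase == phase]
        return out


def _two_bottle_day(
    rng: np.random.Generator,
    pref_water_flavour: float,
    water_flavour: str,
    other_flavour: str,
    mean_licks: float,
    side_first: bool,
) -> Tuple[EventLog, Dict[str, str]]:
    n_total = max(2, int(rng.poisson(mean_licks)))
    n_water = int(rng.binomial(n_total, min(1.0, max(0.0, pref_water_flavour))))
    times = np.sort(rng.uniform(0, 3600.0, n_total))
    which = np.array([water_flavour] * n_water + [other_flavour] * (n_total - n_water))
    rng.shuffle(which)
    records = [(0.0, "access_start", "two_bottle", np.nan)]
    records += [(t, "lick", sol, np.nan) for t, sol in zip(times, which)]
    records.append((3600.0, "access_stop", "two_bottle", np.nan))
    sides = (
        {water_flavour: "front", other_flavour: "back"}
        if side_first
        else {water_flavour: "back", other_flavour: "front"}
    )
    return EventLog.from_records(records), sides


def _training_day(
    rng: np.random.Generator,
    flavour: str,
    infused_solution: str,
    n_licks: int,
) -> EventLog:
    times = np.sort(rng.uniform(0, 3600.0, n_licks))
    records = [(0.0, "access_start", flavour, np.nan)]
    for t in times:
        records.append((t, "lick", flavour, np.nan))
        # closed loop: each training lick triggers a 1 ul infusion of the mapped solution
        records.append((t, "infusion_start", infused_solution, 1.0))
        records.append((t, "infusion_stop", infused_solution, 1.0))
    records.append((3600.0, "access_stop", flavour, np.nan))
    return EventLog.from_records(records)


def gen_training_cohort(
    n_mice_per_group: int = 3,
    learning: Optional[LearningModel] = None,
    seed: int = 0,
    groups: Sequence[int] = (1, 2, 3, 4),
) -> TrainingDataset:
    """Ten-day protocol per mouse: two-bottle tests on days 1–2 (side swapped
    on day 2), six closed-loop training days (3 days per flavour in the
    group's order), two-bottle tests on days 9–10."""
    if n_mice_per_group < 1:
        raise ValueError("need at least one mouse per group")
    lm = learning or LearningModel()
    mice_rows = []
    days: List[MouseDay] = []
    for g in groups:
        mapping = TRAINING_GROUPS[g]
        water_flavour = "grape" if mapping["grape"] == "water" else "lime"
        other_flavour = "lime" if water_flavour == "grape" else "grape"
        for m in range(n_mice_per_group):
            mouse_id = f"g{g}m{m}"
            rng = substream(seed, "mouse", mouse_id)
            pre = float(np.clip(rng.normal(lm.initial_pref_mean, lm.initial_pref_sd), 0, 1))
            drift_total = lm.daily_drift * 6 + (rng.normal(0, lm.drift_sd) if lm.drift_sd > 0 else 0.0)
            post = float(np.clip(pre + drift_total, 0, 1))
            side_first = bool(rng.integers(0, 2))
            for day in (1, 2):
                ev, sides = _two_bottle_day(
                    rng, pre, water_flavour, other_flavour, lm.licks_per_session,
                    side_first if day == 1 else not side_first,
                )
                days.append(MouseDay(mouse_id, day, "two_bottle_pre", None, ev, sides))
            day = 3
            for flavour in mapping["order"]:
                infused = mapping[flavour]
                for _ in range(3):
                    # consumption scales with the mouse's current preference for
                    # this flavour (learned mice drink more of the water-paired one)
                    frac_through = (day - 3) / 5.0
                    pref_now = pre + (post - pre) * frac_through
                    p_flav = pref_now if flavour == water_flavour else 1.0 - pref_now
                    mean_licks = lm.licks_per_session * (
                        0.5 + lm.consumption_gain * (p_flav - 0.5)
                    )
                    n_licks = max(1, int(rng.poisson(max(1.0, mean_licks))))
                    ev = _training_day(rng, flavour, infused, n_licks)
                    days.append(MouseDay(mouse_id, day, "training", flavour, ev))
                    day += 1
            for day in (9, 10):
                ev, sides = _two_bottle_day(
                    rng, post, water_flavour, other_flavour, lm.licks_per_session,
                    side_first if day == 9 else not side_first,
                )
                days.append(MouseDay(mouse_id, day, "two_bottle_post", None, ev, sides))
            mice_rows.append(
                {
                    "mouse_id": mouse_id,
                    "group": g,
                    "water_flavour": water_flavour,
                    "true_pre_pref": pre,
                    "true_post_pref": post,
                }
            )
    return TrainingDataset(mice=pd.DataFrame(mice_rows), days=days)
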