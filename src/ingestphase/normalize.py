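"""Trace and photometry normalization.

Implements the standard preprocessing chain for post-extraction calcium
traces and dual-channel photometry:

* baseline z-scoring, ``z = (C_raw - mu) / sigma`` with mu and sigma taken
  over the baseline period (default: the first 10 min);
* screening out neurons whose baseline carries a large bleaching artifact
  (a well-fitting, large-amplitude decaying exponential);
* a 1/60 Hz zero-phase lowpass extracting the slow "baseline fluorescence"
  component (removes everything faster than one minute);
* isosbestic ΔF/F0 correction: F0 predicted from the ~405 nm reference by a
  linear regression fitted on the baseline window only;
* anti-aliased block-average downsampling (e.g. to 4 Hz for analysis, 1 Hz
  for plotting).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import optimize, signal

from .core import PhotometrySignal, TraceMatrix


@dataclass
class ZTraceMatrix:
    """Baseline z-scored traces with the per-neuron mu/sigma retained."""

    values: np.ndarray
    sample_rate: float
    neuron_ids: List[str]
    baseline_window: Tuple[float, float]
    mu: np.ndarray
    sigma: np.ndarray
    excluded: Dict[str, str] = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) / self.sample_rate


def _window_slice(n_samples: int, sample_rate: float, window: Tuple[float, float]) -> slice:
    start_s, end_s = window
    if start_s < 0 or end_s > n_samples / sample_rate or end_s <= start_s:
        raise ValueError(f"window {window} outside recording")
    i0 = int(round(start_s * sample_rate))
    i1 = int(round(end_s * sample_rate))
    return slice(i0, i1)


def zscore_traces(
    traces: TraceMatrix, baseline_window: Tuple[float, float] = (0.0, 600.0)
) -> ZTraceMatrix:
    """z = (raw - mu)/sigma with mu, sigma (population sd) over the baseline window.

    Neurons with zero baseline sd are degenerate; they are excluded with a
    logged reason rather than producing infinities.
    """
    sl = _window_slice(traces.n_samples, traces.sample_rate, baseline_window)
    if sl.stop - sl.start < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    base = traces.values[:, sl]
    mu = base.mean(axis=1)
    sigma = base.std(axis=1)  # population sd (ddof=0)
    keep = sigma > 0
    excluded = {
        traces.neuron_ids[i]: "zero baseline variance"
        for i in np.flatnonzero(~keep)
    }
    z = (traces.values[keep] - mu[keep, None]) / sigma[keep, None]
    ids = [nid for nid, k in zip(traces.neuron_ids, keep) if k]
    return ZTraceMatrix(
        values=z,
        sample_rate=traces.sample_rate,
        neuron_ids=ids,
        baseline_window=baseline_window,
        mu=mu[keep],
        sigma=sigma[keep],
        excluded=excluded,
    )


@dataclass
class BleachCriteria:
    """Exclusion thresholds for baseline bleaching artifacts (both configurable)."""

    min_r2: float = 0.8
    min_amplitude_sds: float = 2.0


def _exp_decay(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def screen_bleaching(
    traces: TraceMatrix,
    baseline_window: Tuple[float, float] = (0.0, 600.0),
    criteria: Optional[BleachCriteria] = None,
) -> Tuple[List[str], Dict[str, dict]]:
    """Flag neurons whose baseline fits a large decaying exponential.

    A neuron is excluded when the least-squares fit of ``A exp(-t/tau) + c``
    over the baseline explains >= ``min_r2`` of the variance and the fitted
    amplitude A exceeds ``min_amplitude_sds`` residual standard deviations.
    Returns (kept ids, {excluded id: fit diagnostics}).
    """
    crit = criteria or BleachCriteria()
    sl = _window_slice(traces.n_samples, traces.sample_rate, baseline_window)
    if sl.stop - sl.start < 3:
        raise ValueError("baseline window must contain at least 3 samples")
    t = (np.arange(sl.stop - sl.start)) / traces.sample_rate
    span = t[-1] if t[-1] > 0 else 1.0

    kept: List[str] = []
    excluded: Dict[str, dict] = {}
    for nid, y in zip(traces.neuron_ids, traces.values[:, sl]):
        amp0 = y[: max(1, y.size // 10)].mean() - y[-max(1, y.size // 10):].mean()
        p0 = (amp0 if amp0 != 0 else 1.0, span / 3.0, y[-max(1, y.size // 10):].mean())
        try:
            popt, _ = optimize.curve_fit(
                _exp_decay, t, y, p0=p0,
                bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 10 * span, np.inf]),
                maxfev=2000,
            )
        except RuntimeError:
            kept.append(nid)
            continue
        fit = _exp_decay(t, *popt)
        resid = y - fit
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
        resid_sd = float(resid.std())
        amplitude = float(popt[0])
        is_bleach = (
            r2 >= crit.min_r2
            and amplitude > 0
            and resid_sd > 0
            and amplitude >= crit.min_amplitude_sds * resid_sd
        )
        if is_bleach:
            excluded[nid] = {
                "amplitude": amplitude,
                "tau_s": float(popt[1]),
                "offset": float(popt[2]),
                "r2": r2,
                "residual_sd": resid_sd,
            }
        else:
            kept.append(nid)
    return kept, excluded


def baseline_fluorescence(
    traces: TraceMatrix, cutoff_hz: float = 1.0 / 60.0, order: int = 2
) -> np.ndarray:
    """Slow baseline-fluorescence component: zero-phase Butterworth lowpass at
    1/60 Hz (removes all changes faster than one minute); DC preserved."""
    if traces.duration_s() < 120.0:
        raise ValueError("need at least 2 min of data for the 1/60 Hz lowpass")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=traces.sample_rate, output="sos")
    return signal.sosfiltfilt(sos, traces.values, axis=1)


@dataclass
class DffTrace:
    """ΔF/F0 with the baseline regression coefficients retained.

    Samples where the predicted F0 is non-positive are masked (NaN) and
    reported in ``masked_fraction``.
    """

    values: np.ndarray
    sample_rate: float
    slope: float
    intercept: float
    baseline_window: Tuple[float, float]
    masked_fraction: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate


def dff_isosbestic(
    phot: PhotometrySignal, baseline_window: Tuple[float, float] = (0.0, 600.0)
) -> DffTrace:
    """Isosbestic ΔF/F0 correction.

    F_signal is regressed on F_reference over the baseline window (ordinary
    least squares with intercept); F0(t) = a*F_reference(t) + b over the whole
    session; ΔF/F0 = (F - F0)/F0.
    """
    sl = _window_slice(phot.signal.size, phot.sample_rate, baseline_window)
    ref_b = phot.reference[sl]
    sig_b = phot.signal[sl]
    if float(ref_b.std()) == 0.0:
        raise ValueError("reference channel constant over baseline; cannot fit F0 model")
    slope, intercept = np.polyfit(ref_b, sig_b, 1)
    f0 = slope * phot.reference + intercept
    bad = f0 <= 0
    if bad.any():
        warnings.warn(
            f"predicted F0 non-positive for {bad.sum()} samples; masking them", RuntimeWarning
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (phot.signal - f0) / f0
    dff[bad] = np.nan
    return DffTrace(
        values=dff,
        sample_rate=phot.sample_rate,
        slope=float(slope),
        intercept=float(intercept),
        baseline_window=baseline_window,
        masked_fraction=float(bad.mean()),
    )


def downsample(series: np.ndarray, native_rate: float, target_rate: float) -> np.ndarray:
    """Anti-aliased block-average resampling along the last axis.

    Each output sample is the mean of the native samples falling in its bin;
    output length = floor(n * target/native).  Works for non-integer rate
    ratios via bin assignment.
    """
    if target_rate > native_rate:
        raise ValueError("target rate must not exceed the native rate")
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    n_out = int(np.floor(n * target_rate / native_rate))
    if n_out == 0:
        raise ValueError("series too short for requested rate")
    ratio = native_rate / target_rate
    if abs(ratio - round(ratio)) < 1e-9:
        f = int(round(ratio))
        trimmed = x[..., : n_out * f]
        return trimmed.reshape(*x.shape[:-1], n_out, f).mean(axis=-1)
    bins = np.floor(np.arange(n) * target_rate / native_rate).astype(int)
    mask = bins < n_out
    counts = np.bincount(bins[mask], minlength=n_out)
    flat = x.reshape(-1, n)
    out = np.stack([np.bincount(bins[mask], weights=row[mask], minlength=n_out) for row in flat])
    out = out / counts
    return out.reshape(*x.shape[:-1], n_out)


def bandpass_variance(
    series: np.ndarray, sample_rate: float, band: Tuple[float, float] = (0.1, 2.0), order: int = 3
) -> float:
    """Variance of a series restricted to a frequency band (zero-phase
    Butterworth bandpass); used to quantify motion-artifact power."""
    x = np.asarray(series, dtype=float)
    x = np.where(np.isfinite(x), x, np.nanmean(x))
    lo, hi = band
    hi = min(hi, 0.45 * sample_rate)
    sos = signal.butter(order, [lo, hi], btype="band", fs=sample_rate, output="sos")
    return float(np.var(signal.sosfiltfilt(sos, x)))
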