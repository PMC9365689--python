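"""End-to-end orchestration: simulate -> normalize -> behaviour -> classify ->
stats -> machine-readable report.

Reports are deterministic given config + seeds: every open threshold and
window is carried in the config and echoed verbatim into the report, and no
timestamps are written.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import behavior, io, normalize, respond, stats, syngen
from .core import TraceMatrix


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything an end-to-end run depends on, made explicit."""

    modality: str = "imaging"
    manipulation: str = "ig_infusion"
    seed: int = 0
    simulate: bool = True
    traces_path: Optional[str] = None
    events_path: Optional[str] = None
    out_dir: Optional[str] = None

    n_neurons: int = 200
    duration_min: float = 70.0
    baseline_min: float = 10.0
    solution: str = "water"
    infusion_rate_ul_min: float = 100.0
    infusion_volume_ul: float = 1200.0
    fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "oral": 0.22,
            "gi": 0.10,
            "systemic_activated": 0.39,
            "systemic_inhibited": 0.05,
        }
    )
    bleach_fraction: float = 0.0

    analysis_rate_hz: float = 4.0
    epoch_preset: str = "start_anchored"
    classification_mode: str = "simple"
    activation_threshold_z: float = 1.0
    bout_min_duration_s: float = 10.0
    bout_max_gap_s: float = 2.0
    bleach_min_r2: float = 0.8
    bleach_min_amplitude_sds: float = 2.0
    fit_rise: bool = True
    fit_rise_max_neurons: Optional[int] = None
    fit_window_min: float = 45.0


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(name, e) from e
        return wrapped
    return deco


@_stage("simulate")
def _acquire(config: RunConfig):
    if config.simulate:
        design = syngen.SessionDesign(
            modality=config.modality,
            duration_min=config.duration_min,
            baseline_min=config.baseline_min,
            manipulation=config.manipulation,
            infusion_rate_ul_min=config.infusion_rate_ul_min,
            infusion_volume_ul=config.infusion_volume_ul,
            solution=config.solution,
            seed=config.seed,
        )
        noise = syngen.TraceNoise(bleach_fraction=config.bleach_fraction)
        traces, events, truth = syngen.gen_session(
            design,
            fractions=config.fractions,
            noise=noise,
            n_neurons=config.n_neurons,
        )
        return traces, events, truth
    if not config.traces_path or not Path(config.traces_path).exists():
        raise FileNotFoundError(f"traces file not found: {config.traces_path}")
    traces = io.load_traces_h5(config.traces_path)
    events = _load_events(config)
    return traces, events, None


@_stage("behavior")
def _load_events(config: RunConfig):
    if not config.events_path or not Path(config.events_path).exists():
        raise FileNotFoundError(f"events file not found: {config.events_path}")
    return io.load_events_csv(config.events_path)


def _subset(traces: TraceMatrix, keep_ids: List[str]) -> TraceMatrix:
    idx = [traces.neuron_ids.index(i) for i in keep_ids]
    return TraceMatrix(
        values=traces.values[idx],
        sample_rate=traces.sample_rate,
        neuron_ids=keep_ids,
        spikes=traces.spikes[idx] if traces.spikes is not None else None,
    )


def run_session(config: RunConfig) -> dict:
    """Full imaging-session analysis; returns the machine-readable report."""
    traces, events, truth = _acquire(config)
    baseline = (0.0, config.baseline_min * 60.0)

    try:
        kept, bleach_excluded = normalize.screen_bleaching(
            traces,
            baseline,
            normalize.BleachCriteria(config.bleach_min_r2, config.bleach_min_amplitude_sds),
        )
        traces_kept = _subset(traces, kept)
        z = normalize.zscore_traces(traces_kept, baseline)
        z4 = normalize.ZTraceMatrix(
            values=normalize.downsample(z.values, z.sample_rate, config.analysis_rate_hz),
            sample_rate=config.analysis_rate_hz,
            neuron_ids=z.neuron_ids,
            baseline_window=z.baseline_window,
            mu=z.mu,
            sigma=z.sigma,
            excluded=z.excluded,
        )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("normalize", e) from e

    try:
        bouts = behavior.detect_bouts(
            events, config.bout_min_duration_s, config.bout_max_gap_s
        )
    except Exception as e:
        raise PipelineError("behavior", e) from e

    try:
        epochs = respond.define_epochs(
            events, config.modality, config.manipulation,
            preset=config.epoch_preset, baseline_min=config.baseline_min,
        )
        table = respond.classify_population(z4, epochs, mode=config.classification_mode)
        summaries = {
            lab: asdict(respond.population_summary(table, lab))
            for lab in epochs.response_labels()
        }
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("classify", e) from e

    rise_rows = []
    if config.fit_rise and any(l in epochs.windows for l in ("systemic", "ip_systemic")):
        sys_label = "systemic" if "systemic" in epochs.windows else "ip_systemic"
        sys_tab = table[(table["epoch"] == sys_label) & (table["label"] != "none")]
        ids = list(sys_tab["neuron_id"])
        if config.fit_rise_max_neurons is not None:
            ids = ids[: config.fit_rise_max_neurons]
        end_min = min(
            config.fit_window_min,
            (z4.values.shape[1] / z4.sample_rate - epochs.anchor_s) / 60.0,
        )
        for nid in ids:
            i = z4.neuron_ids.index(nid)
            direction = str(
                sys_tab.loc[sys_tab["neuron_id"] == nid, "label"].iloc[0]
            )
            try:
                fit = respond.fit_rise(
                    z4.values[i], z4.sample_rate, epochs.anchor_s,
                    direction=direction, window_min=(0.0, end_min),
                )
            except Exception as e:
                raise PipelineError("fit_rise", e) from e
            rise_rows.append(
                {
                    "neuron_id": nid,
                    "direction": direction,
                    "t50_min": fit.t50_min,
                    "persistence_min": fit.persistence_min,
                    "persistence_censored": fit.persistence_censored,
                    "r2": fit.r2,
                    "converged": fit.converged,
                }
            )

    report = {
        "config": asdict(config),
        "n_neurons_input": traces.n_neurons,
        "excluded_bleach": sorted(bleach_excluded),
        "excluded_degenerate": sorted(z.excluded),
        "n_neurons_analysed": z4.n_neurons,
        "bouts": [list(b) for b in bouts.bouts],
        "first_bout_start_s": bouts.first_bout_start,
        "epochs": {k: list(v) for k, v in epochs.windows.items()},
        "epoch_preset": epochs.preset,
        "anchor_s": epochs.anchor_s,
        "population_summary": summaries,
        "rise_fits": rise_rows,
    }
    if truth is not None:
        n = len(truth.neurons)
        report["ground_truth_fractions"] = {
            a: c / n for a, c in truth.archetype_counts().items()
        }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.save_report(report, out / "session_report.json")
    return report


def run_training_experiment(
    config: Optional[RunConfig] = None,
    n_mice_per_group: int = 3,
    learning: Optional[syngen.LearningModel] = None,
    seed: int = 0,
    sides: int = 1,
) -> dict:
    """Closed-loop flavour-training analysis.

    Per-mouse pre/post preference for the water-paired flavour (lick-weighted
    pooling across the two two-bottle days), a paired permutation test on the
    change (one-sided by default: training should raise preference), and
    per-day consumption totals.
    """
    seed = config.seed if config is not None else seed
    cohort = syngen.gen_training_cohort(n_mice_per_group, learning, seed=seed)
    rows = []
    for m in cohort.mice.itertuples(index=False):
        prefs = {}
        for phase in ("two_bottle_pre", "two_bottle_post"):
            counts = []
            for d in cohort.days_of(m.mouse_id, phase):
                ev = d.events.events
                licks = ev[ev["kind"] == "lick"]
                t = int((licks["solution"] == m.water_flavour).sum())
                o = int((licks["solution"] != m.water_flavour).sum())
                counts.append((t, o))
            pooled, per_day = behavior.two_bottle_preference(counts)
            prefs[phase] = {"pooled": pooled, "per_day": per_day}
        rows.append(
            {
                "mouse_id": m.mouse_id,
                "group": int(m.group),
                "water_flavour": m.water_flavour,
                "pre": prefs["two_bottle_pre"]["pooled"],
                "post": prefs["two_bottle_post"]["pooled"],
                "pre_per_day": prefs["two_bottle_pre"]["per_day"],
                "post_per_day": prefs["two_bottle_post"]["per_day"],
                "true_pre": float(m.true_pre_pref),
                "true_post": float(m.true_post_pref),
            }
        )
    pre = np.array([r["pre"] for r in rows])
    post = np.array([r["post"] for r in rows])
    if len(rows) >= 2:
        test = stats.permutation_test(post, pre, paired=True, sides=sides, seed=seed)
        test_out = {
            "statistic": test.statistic_observed,
            "p": test.p_value,
            "exact": test.exact,
            "sides": sides,
        }
    else:
        test_out = {"error": "fewer than 2 mice; permutation test not run"}
    consumption = behavior.consumption_summary(cohort)
    report = {
        "seed": seed,
        "n_mice": len(rows),
        "mice": rows,
        "mean_pre": float(pre.mean()),
        "mean_post": float(post.mean()),
        "mean_change": float((post - pre).mean()),
        "paired_permutation": test_out,
        "consumption": consumption.to_dict(orient="records"),
    }
    if config is not None and config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.save_report(report, out / "training_report.json")
    return report
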