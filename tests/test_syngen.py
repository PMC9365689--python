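"""Generator correctness: seed determinism, bout ground truth, archetype
rounding, closed-loop conservation, and noiseless waveform recovery."""
import numpy as np
import pandas as pd
import pytest

from ingestphase import behavior, normalize, respond, syngen
from ingestphase.core import substream

from conftest import brute_force_bouts


class TestSessionDesign:
    def test_defaults_per_modality(self):
        assert syngen.SessionDesign(modality="imaging").sample_rate == 8.0
        assert syngen.SessionDesign(modality="photometry").sample_rate == 1017.0

    def test_rejects_duration_inside_baseline(self):
        with pytest.raises(ValueError, match="duration"):
            syngen.SessionDesign(duration_min=5.0, baseline_min=10.0)

    def test_infusion_fields_required(self):
        with pytest.raises(ValueError, match="infusion"):
            syngen.SessionDesign(manipulation="ig_infusion", infusion_volume_ul=None)


class TestLickTrain:
    def test_forced_single_bout(self):
        # 0.5 s intervals for >= 10 s then silence: exactly one true bout
        design = syngen.SessionDesign(manipulation="drinking", duration_min=30, seed=0)
        bp = syngen.LickBoutParams(
            access_start_s=600.0, access_duration_s=25.0,
            bout_rate_per_min=2.0, bout_duration_mean_s=20.0, bout_duration_sd_s=0.0,
            ili_min_s=0.5, ili_max_s=0.5,
        )
        log, truth = syngen.gen_lick_train(design, bp, seed=1)
        assert len(truth) == 1
        start, end, n = truth[0]
        assert end - start >= 10.0
        assert n == pytest.approx((end - start) / 0.5 + 1)

    def test_zero_rate_empty(self):
        design = syngen.SessionDesign(manipulation="drinking", duration_min=30, seed=0)
        bp = syngen.LickBoutParams(bout_rate_per_min=0.0)
        log, truth = syngen.gen_lick_train(design, bp)
        assert log.lick_times().size == 0
        assert truth == []

    def test_access_window_outside_session_rejected(self):
        design = syngen.SessionDesign(manipulation="drinking", duration_min=20, seed=0)
        bp = syngen.LickBoutParams(access_start_s=1100.0, access_duration_s=200.0)
        with pytest.raises(ValueError, match="access window"):
            syngen.gen_lick_train(design, bp)

    def test_licks_inside_access_window(self):
        design = syngen.SessionDesign(manipulation="drinking", duration_min=30, seed=5)
        bp = syngen.LickBoutParams(access_start_s=600.0, access_duration_s=300.0)
        log, _ = syngen.gen_lick_train(design, bp)
        t = log.lick_times()
        assert np.all(t >= 600.0) and np.all(t <= 900.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_generator_truth_matches_detector(self, seed):
        design = syngen.SessionDesign(manipulation="drinking", duration_min=30, seed=seed)
        log, truth = syngen.gen_lick_train(design)
        detected = behavior.detect_bouts(log).bouts
        assert [(pytest.approx(a), pytest.approx(b), c) for a, b, c in truth] == detected


class TestPopulation:
    def test_largest_remainder_exact(self):
        counts = syngen.largest_remainder_counts(10, {"systemic_activated": 0.4})
        assert counts["systemic_activated"] == 4
        assert counts["none"] == 6

    def test_largest_remainder_tie_break_by_enum_order(self):
        # two archetypes with identical remainders: the earlier-declared wins
        counts = syngen.largest_remainder_counts(10, {"oral": 0.25, "gi": 0.25})
        assert counts["oral"] + counts["gi"] == 5
        assert counts["oral"] == 3  # oral precedes gi in the archetype order

    def test_all_zero_fractions(self):
        truth = syngen.gen_population(20, {}, seed=0)
        assert set(truth.neurons["archetype"]) == {"none"}

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            syngen.gen_population(10, {"oral": -0.1})

    def test_counts_follow_fractions(self):
        fr = {"oral": 0.22, "gi": 0.10, "systemic_activated": 0.39, "systemic_inhibited": 0.05}
        truth = syngen.gen_population(200, fr, seed=3)
        counts = truth.archetype_counts()
        assert counts["oral"] == 44
        assert counts["systemic_activated"] == 78
        assert counts["none"] == 48


class TestSeedDeterminism:
    def test_traces_bit_identical(self):
        design = syngen.SessionDesign(seed=9, duration_min=30)
        a = syngen.gen_session(design, n_neurons=20)
        b = syngen.gen_session(design, n_neurons=20)
        assert np.array_equal(a[0].values, b[0].values)
        assert a[1].events.equals(b[1].events)
        assert a[2].neurons.equals(b[2].neurons)

    def test_adding_neurons_does_not_perturb_existing(self):
        design = syngen.SessionDesign(seed=9, duration_min=30)
        fr = {"systemic_activated": 1.0}
        ev, _ = syngen.gen_events(design)
        t_small = syngen.gen_population(10, fr, seed=9)
        t_big = syngen.gen_population(15, fr, seed=9)
        small = syngen.gen_traces(t_small, ev, design)
        big = syngen.gen_traces(t_big, ev, design)
        assert np.array_equal(small.values, big.values[:10])

    def test_substreams_differ(self):
        a = substream(1, "x").standard_normal(5)
        b = substream(1, "y").standard_normal(5)
        assert not np.allclose(a, b)


class TestTraces:
    def test_flat_trace_for_none_archetype_no_noise(self):
        design = syngen.SessionDesign(seed=0, duration_min=30)
        ev, _ = syngen.gen_events(design)
        truth = syngen.gen_population(3, {}, seed=0)
        tr = syngen.gen_traces(truth, ev, design, noise=syngen.TraceNoise(noise_sd=0.0))
        assert np.allclose(tr.values, tr.values[:, :1])

    def test_noiseless_systemic_t50_matches_onset(self):
        design = syngen.SessionDesign(seed=2, duration_min=70)
        ev, _ = syngen.gen_events(design)
        truth = syngen.gen_population(4, {"systemic_activated": 1.0}, seed=2)
        tr = syngen.gen_traces(
            truth, ev, design, noise=syngen.TraceNoise(noise_sd=1e-6)
        )
        z = normalize.zscore_traces(tr, (0, 600))
        anchor = ev.first("infusion_start")
        for i, row in truth.neurons.iterrows():
            fit = respond.fit_rise(z.values[i], 8.0, anchor, "activated", (0.0, 58.0))
            assert fit.t50_min == pytest.approx(row["onset_min"], abs=1 / 8 / 60 + 0.02)
            assert fit.persistence_min == pytest.approx(row["persistence_min"], abs=0.5)

    def test_epoch_means_match_waveform_integral(self):
        # mean z over the systemic epoch should equal amplitude x the analytic
        # mean of the injected logistic-product waveform over that window
        design = syngen.SessionDesign(seed=7, duration_min=70)
        ev, _ = syngen.gen_events(design)
        truth = syngen.gen_population(6, {"systemic_activated": 1.0}, seed=7)
        tr = syngen.gen_traces(truth, ev, design, noise=syngen.TraceNoise(noise_sd=1e-6))
        z = normalize.zscore_traces(tr, (0, 600))
        ep = respond.define_epochs(ev, "imaging", "ig_infusion")
        means = respond.epoch_response(z, ep["systemic"])
        t = np.arange(tr.n_samples) / 8.0
        i0, i1 = int(ep["systemic"][0] * 8), int(ep["systemic"][1] * 8)
        for i, row in truth.neurons.iterrows():
            w = syngen.systemic_waveform(
                t, ep.anchor_s, row["onset_min"], row["persistence_min"]
            )
            expect = row["peak_amplitude"] * w[i0:i1].mean()
            assert means[i] == pytest.approx(expect, rel=0.02, abs=0.02)

    def test_gi_responders_elevated_during_infusion_only(self):
        design = syngen.SessionDesign(seed=4, duration_min=70)
        ev, _ = syngen.gen_events(design)
        truth = syngen.gen_population(5, {"gi": 1.0}, seed=4)
        tr = syngen.gen_traces(truth, ev, design, noise=syngen.TraceNoise(noise_sd=1e-6))
        z = normalize.zscore_traces(tr, (0, 600))
        ep = respond.define_epochs(ev, "imaging", "ig_infusion")
        gi = respond.epoch_response(z, ep["gastrointestinal"])
        late = respond.epoch_response(z, (ep["systemic"][0] + 300, ep["systemic"][1]))
        assert np.all(gi > 1.0)
        assert np.all(late < 0.5)

    def test_incompatible_kinetics_rejected(self):
        design = syngen.SessionDesign(manipulation="drinking", duration_min=30, seed=0,
                                      sample_rate=0.5)
        ev, _ = syngen.gen_events(design)
        truth = syngen.gen_population(2, {"oral": 1.0}, seed=0)
        with pytest.raises(ValueError, match="sample rate|kinetics"):
            syngen.gen_traces(truth, ev, design)


class TestPhotometry:
    def test_zero_weights_zero_artifact_flat_dff(self):
        design = syngen.SessionDesign(
            modality="photometry", duration_min=30, seed=1, infusion_volume_ul=600.0
        )
        ev, _ = syngen.gen_events(design)
        phot = syngen.gen_photometry(
            syngen.RegionProfile(), ev, design,
            syngen.ArtifactParams(walk_sd=0.0, channel_noise_sd=1e-9),
        )
        dff = normalize.dff_isosbestic(phot, (0, 600))
        assert np.nanmax(np.abs(dff.values)) < 1e-6

    def test_oral_profile_peaks_at_bouts_not_late(self):
        design = syngen.SessionDesign(
            modality="photometry", manipulation="drinking", duration_min=60,
            seed=3, sample_rate=100.0,
        )
        ev, truth_bouts = syngen.gen_events(design)
        phot = syngen.gen_photometry(
            syngen.RegionProfile(oral=0.1), ev, design,
            syngen.ArtifactParams(walk_sd=0.0, channel_noise_sd=1e-4),
        )
        dff = normalize.dff_isosbestic(phot, (0, 600))
        first_bout = truth_bouts[0][0]
        i_b = int(first_bout * 100)
        peak_window = dff.values[i_b : i_b + 30 * 100]
        late = dff.values[int((first_bout + 12 * 60) * 100):]
        assert peak_window.max() > 0.05
        assert np.nanmax(np.abs(late)) < 0.01


class TestAccelerometer:
    def test_schedule_shape(self):
        acc = syngen.gen_accelerometer([(5, 10)], 20.0, seed=0)
        assert acc.axes.shape == (3, 1000)
        assert acc.sample_rate == 50.0

    def test_bout_outside_session_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            syngen.gen_accelerometer([(5, 30)], 20.0)


class TestTrainingCohort:
    def test_closed_loop_conservation(self):
        cohort = syngen.gen_training_cohort(2, seed=1)
        for d in cohort.days:
            if d.phase != "training":
                continue
            ev = d.events.events
            licks = int((ev["kind"] == "lick").sum())
            infusions = int((ev["kind"] == "infusion_start").sum())
            volume = float(ev.loc[ev["kind"] == "infusion_start", "volume_ul"].sum())
            assert infusions == licks
            assert volume == pytest.approx(licks * 1.0)

    def test_group_structure(self):
        cohort = syngen.gen_training_cohort(1, seed=0)
        assert sorted(cohort.mice["group"]) == [1, 2, 3, 4]
        # groups 3 and 4 pair grape with water, 1 and 2 pair lime with water
        wf = cohort.mice.set_index("group")["water_flavour"]
        assert wf[1] == "lime" and wf[2] == "lime"
        assert wf[3] == "grape" and wf[4] == "grape"

    def test_two_bottle_sides_reverse_across_days(self):
        cohort = syngen.gen_training_cohort(1, seed=2)
        m = cohort.mice["mouse_id"].iloc[0]
        d1, d2 = cohort.days_of(m, "two_bottle_pre")
        assert d1.side_of_flavour != d2.side_of_flavour

    def test_zero_drift_preference_unchanged_in_expectation(self):
        lm = syngen.LearningModel(daily_drift=0.0, drift_sd=0.0)
        changes = []
        for seed in range(10):
            cohort = syngen.gen_training_cohort(3, lm, seed=seed)
            changes.append(
                (cohort.mice["true_post_pref"] - cohort.mice["true_pre_pref"]).mean()
            )
        assert np.mean(changes) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_full_learning(self):
        lm = syngen.LearningModel(initial_pref_mean=0.5, initial_pref_sd=0.0,
                                  daily_drift=1.0, drift_sd=0.0)
        cohort = syngen.gen_training_cohort(1, lm, seed=0)
        assert np.all(cohort.mice["true_post_pref"] == 1.0)
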