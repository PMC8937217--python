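"""Epoch windows, event probability, evoked amplitude, display products."""

import numpy as np
import pandas as pd
import pytest

import pomtrace as pt
from conftest import make_trial_table
from test_events import events_from_onsets


class TestAssignEpochWindows:
    def test_canonical_window_arithmetic(self):
        trials = make_trial_table(1, outcomes=["HIT"])
        win = pt.assign_epoch_windows(trials).set_index("epoch")
        assert (win.loc["spontaneous", ["win_start", "win_end"]] == [1.0, 2.0]).all()
        assert (win.loc["response", ["win_start", "win_end"]] == [3.0, 4.0]).all()
        assert (win.loc["reward", ["win_start", "win_end"]] == [4.5, 5.5]).all()

    def test_miss_trial_has_no_reward_window(self):
        trials = make_trial_table(2, outcomes=["HIT", "MISS"])
        win = pt.assign_epoch_windows(trials)
        assert "reward" in set(win[win.trial_id == 0]["epoch"])
        assert "reward" not in set(win[win.trial_id == 1]["epoch"])

    def test_catch_trials_use_virtual_stimulus_time(self):
        trials = make_trial_table(1, outcomes=["CR"])
        trials.loc[0, "t_stimulus"] = np.nan  # no recorded stimulus on a catch trial
        win = pt.assign_epoch_windows(trials).set_index("epoch")
        assert (win.loc["response", ["win_start", "win_end"]] == [3.0, 4.0]).all()

    def test_split_stimulus_response_windows(self):
        trials = make_trial_table(1)
        win = pt.assign_epoch_windows(trials, pt.canonical_epochs(split_stimulus=True))
        w = win.set_index("epoch")
        assert (w.loc["stimulus", ["win_start", "win_end"]] == [3.0, 3.5]).all()
        assert (w.loc["response", ["win_start", "win_end"]] == [3.5, 4.0]).all()


class TestEventProbability:
    def test_twelve_of_forty_hit_trials_is_030(self):
        trials = make_trial_table(40, outcomes=["HIT"] * 40)
        windows = pt.assign_epoch_windows(trials)
        events = events_from_onsets({"a": {t: [3.2] for t in range(12)}})
        stats = pt.event_probability(events, windows, trials, ["a"])
        row = stats[(stats.epoch == "response") & (stats.outcome == "HIT")].iloc[0]
        assert row.probability == pytest.approx(0.30)
        assert row.n_trials == 40 and row.n_event_trials == 12

    def test_multiple_onsets_in_one_trial_count_once(self):
        trials = make_trial_table(10)
        windows = pt.assign_epoch_windows(trials)
        events = events_from_onsets({"a": {0: [3.1, 3.5, 3.9]}})
        stats = pt.event_probability(events, windows, trials, ["a"])
        row = stats[(stats.epoch == "response")].iloc[0]
        assert row.probability == pytest.approx(0.1)

    def test_no_events_gives_zero_probability(self):
        trials = make_trial_table(5)
        windows = pt.assign_epoch_windows(trials)
        stats = pt.event_probability(events_from_onsets({}), windows, trials, ["a"])
        assert (stats.probability == 0).all()

    def test_zero_eligible_trials_yields_no_row_not_zero(self):
        trials = make_trial_table(4, outcomes=["MISS"] * 4)  # never rewarded
        windows = pt.assign_epoch_windows(trials)
        stats = pt.event_probability(events_from_onsets({}), windows, trials, ["a"])
        assert "reward" not in set(stats.epoch)

    def test_probability_invariant_to_trial_duplication(self):
        trials = make_trial_table(8, outcomes=["HIT"] * 8)
        windows = pt.assign_epoch_windows(trials)
        events = events_from_onsets({"a": {t: [3.3] for t in range(4)}})
        base = pt.event_probability(events, windows, trials, ["a"])
        doubled_trials = make_trial_table(16, outcomes=["HIT"] * 16)
        doubled_windows = pt.assign_epoch_windows(doubled_trials)
        doubled_events = events_from_onsets(
            {"a": {t: [3.3] for t in list(range(4)) + list(range(8, 12))}}
        )
        doubled = pt.event_probability(doubled_events, doubled_windows, doubled_trials, ["a"])
        for epoch in ("response", "spontaneous"):
            a = base[base.epoch == epoch].probability.iloc[0]
            b = doubled[doubled.epoch == epoch].probability.iloc[0]
            assert a == b
        assert (base.probability <= 1).all()

    def test_generator_probability_recovery(self, rng):
        cfg = pt.SimConfig(
            n_trials=100, n_axons=40, catch_fraction=0.0, hit_rate=1.0, seed=17,
            epoch_event_prob={"response": 0.5},
        )
        session = pt.simulate_session(cfg)
        res = pt.analyze_session(session.traces, session.trials, dedup=False)
        probs = pt.pipeline.mean_epoch_probabilities(res.epoch_stats, "HIT")
        from oracles import binom_ci99

        lo, hi = binom_ci99(0.5, 40 * 100)
        assert lo <= probs["response"] <= hi


class TestEvokedAmplitude:
    def test_single_event_mean_is_its_peak(self):
        trials = make_trial_table(5)
        windows = pt.assign_epoch_windows(trials)
        events = events_from_onsets({"a": {0: [3.2]}}, peaks={"a": 0.8})
        stats = pt.evoked_amplitude_stats(events, windows, trials)
        row = stats[stats.epoch == "response"].iloc[0]
        assert row.mean_peak_dff == pytest.approx(0.8)

    def test_mean_over_event_trials(self):
        trials = make_trial_table(5)
        windows = pt.assign_epoch_windows(trials)
        events = pd.concat(
            [
                events_from_onsets({"a": {0: [3.2]}}, peaks={"a": 0.5}),
                events_from_onsets({"a": {1: [3.4]}}, peaks={"a": 1.5}),
            ]
        )
        stats = pt.evoked_amplitude_stats(events, windows, trials)
        assert stats[stats.epoch == "response"].iloc[0].mean_peak_dff == pytest.approx(1.0)

    def test_first_event_per_trial_epoch_is_used(self):
        trials = make_trial_table(3)
        windows = pt.assign_epoch_windows(trials)
        events = pd.DataFrame(
            {
                "roi_id": ["a", "a"],
                "trial_id": [0, 0],
                "onset_s": [3.6, 3.1],
                "offset_s": [4.0, 3.5],
                "peak_dff": [2.0, 1.0],
                "duration_ms": [400.0, 400.0],
            }
        )
        stats = pt.evoked_amplitude_stats(events, windows, trials)
        assert stats[stats.epoch == "response"].iloc[0].mean_peak_dff == 1.0

    def test_amplitude_recovery_from_generator(self, rng):
        """Injected lognormal amplitude mean is recovered within 2 SE."""
        cfg = pt.SimConfig(
            n_trials=60, n_axons=20, catch_fraction=0.0, hit_rate=1.0, seed=23,
            noise_sd=1.0, drift_amplitude=0.0, amplitude_mean=1.0, amplitude_sd=0.3,
            epoch_event_prob={"response": 0.5},
        )
        session = pt.simulate_session(cfg)
        res = pt.analyze_session(session.traces, session.trials, dedup=False)
        amp = pt.pipeline.mean_epoch_amplitudes(res.epoch_stats, "HIT")["response"]
        n_events = len(res.events)
        se = 0.3 / np.sqrt(n_events)
        assert abs(amp - 1.0) < max(2 * se, 0.02)


class TestCategorizeAxons:
    def _avg(self, peaks_at, n_samples=255, rate=30.0):
        times = np.arange(n_samples) / rate
        traces = np.zeros((len(peaks_at), n_samples))
        for i, t_peak in enumerate(peaks_at):
            if t_peak is not None:
                traces[i] = np.exp(-((times - t_peak) ** 2) / (2 * 0.15**2))
        return traces, times

    def test_peak_locations_map_to_epochs(self):
        traces, times = self._avg([3.4, 1.5, 4.9, None])
        labels = pt.categorize_axons_by_peak(traces, times, ["a", "b", "c", "d"])
        assert labels["a"] == "response"
        assert labels["b"] == "spontaneous"
        assert labels["c"] == "reward"
        assert labels["d"] == "none"  # flat trace

    def test_peak_outside_all_windows_is_none(self):
        traces, times = self._avg([6.5])
        assert pt.categorize_axons_by_peak(traces, times, ["a"])["a"] == "none"

    def test_generator_reward_axons_are_labeled_reward(self, rng):
        cfg = pt.SimConfig(
            n_trials=40, n_axons=6, catch_fraction=0.0, hit_rate=1.0, seed=29,
            noise_sd=1.0, epoch_event_prob={"reward": {"HIT": 0.9}},
        )
        session = pt.simulate_session(cfg)
        res = pt.analyze_session(session.traces, session.trials, dedup=False)
        hit_mask = res.trials["outcome"].to_numpy() == "HIT"
        avg = res.dff.trial_average(hit_mask)
        labels = pt.categorize_axons_by_peak(avg, res.dff.sample_times, res.dff.roi_ids)
        assert (labels == "reward").mean() >= 0.8


class TestMassAverageAndDisplay:
    def test_identical_traces_have_zero_sem(self):
        dff = np.ones((3, 4, 50))
        mean, sem = pt.mass_average(dff)
        assert np.allclose(mean, 1.0) and np.allclose(sem, 0.0)

    def test_mean_of_constant_rois(self):
        dff = np.stack([np.zeros((4, 50)), np.ones((4, 50))])
        mean, _ = pt.mass_average(dff)
        assert np.allclose(mean, 0.5)

    def test_linearity(self, rng):
        dff = rng.normal(0, 1, (5, 6, 40))
        mean1, _ = pt.mass_average(dff)
        mean2, _ = pt.mass_average(3.0 * dff)
        np.testing.assert_allclose(mean2, 3.0 * mean1, rtol=1e-12)

    def test_display_matrix_normalizes_and_sorts(self):
        times = np.arange(120) / 30.0
        rows = []
        for t_peak, amp in ((1.0, 2.0), (3.0, 0.5), (2.0, 1.5)):
            rows.append(amp * np.exp(-((times - t_peak) ** 2) / 0.02))
        matrix, order = pt.display_matrix(np.asarray(rows), times, ["r0", "r1", "r2"])
        assert order == ["r0", "r2", "r1"]  # peak times 1 s, 2 s, 3 s
        np.testing.assert_allclose(matrix.max(axis=1), 1.0)

    def test_equal_peak_times_keep_stable_id_order(self):
        times = np.arange(60) / 30.0
        row = np.exp(-((times - 1.0) ** 2) / 0.02)
        matrix, order = pt.display_matrix(np.stack([row, row]), times, ["z", "a"])
        assert order == ["a", "z"]

    def test_nonpositive_rows_dropped(self):
        times = np.arange(30) / 30.0
        good = np.exp(-((times - 0.5) ** 2) / 0.01)
        bad = -np.ones_like(times)
        matrix, order = pt.display_matrix(np.stack([good, bad]), times, ["g", "b"])
        assert order == ["g"] and matrix.shape[0] == 1
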