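"""Transient detection (threshold + duration rule) and duplicate-ROI removal."""

import numpy as np
import pandas as pd
import pytest

import pomtrace as pt
from conftest import make_aligned, make_baseline
from oracles import brute_force_events


def detect_single(x, f0=100.0, sd=5.0, rate=30.0, **kwargs):
    aligned = make_aligned(np.asarray(x, dtype=float)[None, None, :], frame_rate=rate)
    baseline = make_baseline([[f0]], [sd], n_trials=1)
    return pt.detect_events(aligned, baseline, **kwargs)


class TestDetectEvents:
    def test_flat_zero_trace_has_no_events(self):
        assert detect_single(np.zeros(300)).empty

    def test_duration_rule_is_strictly_greater_than_200ms(self):
        # threshold = 2*5/100 = 0.1 dF/F; 6 samples at 30 Hz last exactly 200 ms
        six = np.zeros(60)
        six[10:16] = 1.0
        assert detect_single(six).empty
        seven = np.zeros(60)
        seven[10:17] = 1.0
        events = detect_single(seven)
        assert len(events) == 1
        ev = events.iloc[0]
        assert ev.onset_s == pytest.approx(10 / 30)
        assert ev.offset_s == pytest.approx(17 / 30)
        assert ev.duration_ms == pytest.approx(7000 / 30)
        assert ev.peak_dff == 1.0

    def test_missing_samples_split_runs(self):
        x = np.zeros(80)
        x[10:30] = 1.0
        x[19] = np.nan  # gap splits a 20-sample run into 9 + 10 samples
        events = detect_single(x)
        assert len(events) == 2
        assert events.iloc[0].offset_s == pytest.approx(19 / 30)
        assert events.iloc[1].onset_s == pytest.approx(20 / 30)

    def test_run_touching_trace_end_is_closed_one_sample_past(self):
        x = np.zeros(40)
        x[-10:] = 1.0
        events = detect_single(x)
        assert len(events) == 1
        assert events.iloc[0].offset_s == pytest.approx(40 / 30)

    def test_matches_brute_force_oracle_on_random_traces(self, rng):
        """Vectorized detector vs an exhaustive run-length scan, 200 mixed-SNR traces."""
        n_traces, n_samples, rate = 200, 255, 30.0
        kernel = pt.calcium_kernel(rate, 50, 400)
        f0s = rng.uniform(60, 140, n_traces)
        sds = rng.uniform(2, 10, n_traces)
        mismatches = 0
        for i in range(n_traces):
            x = rng.normal(0, rng.uniform(0.02, 0.25), n_samples)
            for _ in range(rng.integers(0, 4)):
                onset = rng.integers(0, n_samples - 5)
                amp = rng.uniform(0.1, 2.0)
                seg = min(len(kernel), n_samples - onset)
                x[onset : onset + seg] += amp * kernel[:seg]
            thr = 2 * sds[i] / f0s[i]
            expected = brute_force_events(x, thr, 1 / rate)
            got = detect_single(x, f0=f0s[i], sd=sds[i], rate=rate)
            if len(got) != len(expected):
                mismatches += 1
                continue
            for row, (i0, i1, peak) in zip(got.itertuples(), expected):
                if not (
                    np.isclose(row.onset_s, i0 / rate)
                    and np.isclose(row.offset_s, i1 / rate)
                    and np.isclose(row.peak_dff, peak)
                ):
                    mismatches += 1
        assert mismatches == 0

    def test_detection_count_monotone_in_amplitude(self, rng):
        noise = rng.normal(0, 0.05, (1, 30, 255))
        kernel = pt.calcium_kernel(30.0, 50, 400)
        counts = []
        for amp in (0.05, 0.3, 1.0):
            x = noise.copy()
            for t in range(30):
                x[0, t, 90 : 90 + len(kernel)][: min(len(kernel), 165)] += (
                    amp * kernel[: min(len(kernel), 165)]
                )
            aligned = make_aligned(x)
            baseline = make_baseline([[100.0]], [5.0], n_trials=30)
            counts.append(len(pt.detect_events(aligned, baseline)))
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] == 30


class TestActiveRois:
    def test_silent_roi_is_inactive(self):
        events = pd.DataFrame({"roi_id": ["a"], "trial_id": [0], "onset_s": [1.0],
                               "offset_s": [1.5], "peak_dff": [0.5], "duration_ms": [500.0]})
        assert pt.flag_active_rois(events, ["a", "b"]) == ["a"]

    def test_single_spontaneous_event_counts(self):
        events = pd.DataFrame({"roi_id": ["b"], "trial_id": [3], "onset_s": [1.2],
                               "offset_s": [1.6], "peak_dff": [0.4], "duration_ms": [400.0]})
        assert "b" in pt.flag_active_rois(events, ["a", "b"])

    def test_recovers_ground_truth_active_set_at_high_snr(self, rng):
        """Axons the generator left silent are the ones flagged inactive."""
        cfg = pt.SimConfig(n_trials=30, n_axons=10, seed=21, noise_sd=2.0)
        trials = pt.simulate_trials(cfg, rng)
        traces, gt = pt.simulate_traces(trials, cfg, rng)
        # silence 2 axons by zeroing their dF/F signal back to baseline level
        silent = ["axon000.0", "axon001.0"]
        for roi in silent:
            i = traces.roi_ids.index(roi)
            traces.values[i] = cfg.f0_level + rng.normal(0, cfg.noise_sd, traces.values.shape[1])
            gt.true_events[roi] = []
        res = pt.analyze_session(traces, trials, dedup=False)
        truly_active = {r for r, v in gt.true_events.items() if len(v) > 0}
        assert set(res.active_rois) == truly_active


def events_from_onsets(onsets_by_roi, peaks=None):
    """Build an event table from {roi: {trial: [onset, ...]}}."""
    rows = []
    for roi, by_trial in onsets_by_roi.items():
        for trial, onsets in by_trial.items():
            for onset in onsets:
                rows.append(
                    {
                        "roi_id": roi,
                        "trial_id": trial,
                        "onset_s": onset,
                        "offset_s": onset + 0.4,
                        "peak_dff": (peaks or {}).get(roi, 1.0),
                        "duration_ms": 400.0,
                    }
                )
    return pd.DataFrame(rows)


class TestDeduplicateRois:
    def test_exact_copy_is_removed(self):
        by_trial = {t: [3.1] for t in range(20)}
        events = events_from_onsets({"a": by_trial, "b": by_trial}, peaks={"a": 1.0, "b": 0.8})
        res = pt.deduplicate_rois(events, np.arange(20), ["a", "b"])
        assert res.pairwise_agreement.loc["a", "b"] == 1.0
        assert res.duplicate_groups == [["a", "b"]]
        assert res.kept_roi_ids == ["a"]  # higher mean peak survives

    def test_independent_rois_both_kept_with_expected_agreement(self, rng):
        """Two ROIs firing independently at p=0.3/trial agree only by chance.

        Chance agreement = P(neither) + P(both & onsets within tolerance)
        = 0.7^2 + 0.3^2 * p_match, far below the 0.95 linkage threshold.
        """
        n_trials, p, window = 300, 0.3, 8.0
        onsets = {}
        for roi in ("a", "b"):
            onsets[roi] = {
                t: [rng.uniform(0, window)] for t in range(n_trials) if rng.random() < p
            }
        events = events_from_onsets(onsets)
        res = pt.deduplicate_rois(events, np.arange(n_trials), ["a", "b"])
        assert res.kept_roi_ids == ["a", "b"] and res.duplicate_groups == []
        tol_s = 2 / 30.0
        p_match = 2 * tol_s / window  # near-uniform onset-difference approximation
        expected = (1 - p) ** 2 + p * p * p_match
        assert res.pairwise_agreement.loc["a", "b"] == pytest.approx(expected, abs=0.08)

    def test_three_branches_form_one_group_with_one_survivor(self):
        by_trial = {t: [2.0 + 0.1 * t] for t in range(15)}
        jittered = {t: [o + 1 / 30] for t, (o,) in ((t, v) for t, v in by_trial.items())}
        events = events_from_onsets(
            {"a": by_trial, "b": by_trial, "c": jittered}, peaks={"a": 0.9, "b": 1.2, "c": 1.0}
        )
        res = pt.deduplicate_rois(events, np.arange(15), ["a", "b", "c"])
        assert res.duplicate_groups == [["a", "b", "c"]]
        assert res.kept_roi_ids == ["b"]

    def test_single_trial_session_skips_with_warning(self):
        events = events_from_onsets({"a": {0: [1.0]}, "b": {0: [1.0]}})
        with pytest.warns(UserWarning, match="single-trial"):
            res = pt.deduplicate_rois(events, np.array([0]), ["a", "b"])
        assert res.kept_roi_ids == ["a", "b"]

    def test_removal_never_alters_kept_roi_events(self, rng):
        cfg = pt.SimConfig(n_trials=25, n_axons=5, branches_per_axon=2, seed=31)
        session = pt.simulate_session(cfg)
        res = pt.analyze_session(session.traces, session.trials, dedup=True)
        kept = set(res.dedup.kept_roi_ids)
        before = res.all_events[res.all_events["roi_id"].isin(kept)].reset_index(drop=True)
        pd.testing.assert_frame_equal(before, res.events)
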