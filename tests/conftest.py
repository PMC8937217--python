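import numpy as np
import pandas as pd
import pytest

import pomtrace as pt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_config():
    """A quick, high-SNR session: 20 trials, 6 axons."""
    return pt.SimConfig(n_trials=20, n_axons=6, seed=11)


@pytest.fixture(scope="module")
def session():
    """A moderately sized session shared by read-only tests."""
    cfg = pt.SimConfig(n_trials=40, n_axons=12, seed=3)
    return pt.simulate_session(cfg)


def make_trial_table(
    n_trials: int,
    outcomes: list[str] | None = None,
    trial_types: list[str] | None = None,
    spacing_s: float = 14.0,
    task_mode: str = "action",
) -> pd.DataFrame:
    """Hand-built trial table with the standard timing skeleton."""
    rows = []
    for i in range(n_trials):
        outcome = outcomes[i] if outcomes else "HIT"
        ttype = trial_types[i] if trial_types else ("catch" if outcome in ("FA", "CR") else "stimulus")
        t_start = 5.0 + i * spacing_s
        rewarded = outcome == "HIT"
        rows.append(
            {
                "trial_id": i,
                "trial_type": ttype,
                "t_start": t_start,
                "t_stimulus": t_start + 3.0,
                "t_reward": t_start + 4.5 if rewarded else np.nan,
                "lick_times": [],
                "outcome": outcome,
                "task_mode": task_mode,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture()
def trial_table():
    return make_trial_table


def make_aligned(dff_array, frame_rate=30.0, trial_ids=None, roi_ids=None):
    """Wrap a (rois, trials, samples) array as TrialAlignedTraces."""
    dff_array = np.asarray(dff_array, dtype=float)
    n_rois, n_trials, n_samples = dff_array.shape
    return pt.TrialAlignedTraces(
        dff_array,
        np.arange(n_samples) / frame_rate,
        np.arange(n_trials) if trial_ids is None else np.asarray(trial_ids),
        [f"roi{i:03d}" for i in range(n_rois)] if roi_ids is None else roi_ids,
        frame_rate,
    )


def make_baseline(f0, sd, n_trials=None, roi_ids=None, rolling_window=5):
    """Wrap per-ROI constants as a BaselineSeries."""
    f0 = np.atleast_2d(np.asarray(f0, dtype=float))
    sd = np.atleast_1d(np.asarray(sd, dtype=float))
    if n_trials is not None and f0.shape[1] == 1:
        f0 = np.repeat(f0, n_trials, axis=1)
    n_rois = f0.shape[0]
    return pt.BaselineSeries(
        f0,
        sd,
        f0.copy(),
        rolling_window,
        [f"roi{i:03d}" for i in range(n_rois)] if roi_ids is None else roi_ids,
        np.arange(f0.shape[1]),
    )


@pytest.fixture()
def aligned_factory():
    return make_aligned


@pytest.fixture()
def baseline_factory():
    return make_baseline
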