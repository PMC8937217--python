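"""Per-epoch event statistics, axon categorization, and display matrices.

Three behaviorally relevant 1-s epochs anchor the analysis:
*spontaneous* activity in [-2, -1) s relative to stimulus onset,
*response* activity in [0, +1) s relative to stimulus onset (the
stimulus and response sub-windows, [0, 0.5) and [0.5, 1.0), are merged
by default), and *reward* activity in [0, +1) s relative to reward
delivery, which exists only on rewarded trials.  Catch trials anchor
their windows to the virtual stimulus time (trial start + 3 s).

The headline statistic is the per-trial transient probability per ROI,
epoch and outcome class: the fraction of eligible trials with at least
one event onset inside the epoch window (sum of event-trials over sum
of trials).  A trial with several onsets in the window counts once, so
the statistic is a probability bounded by 1.  Evoked amplitude and
duration are averaged over the first event of each event-trial, over
ROIs that had at least one event in the epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import REWARD_ONSET_S, STIM_ONSET_S
from .errors import PomtraceError

logger = logging.getLogger(__name__)

EPOCH_STAT_COLUMNS = [
    "roi_id",
    "epoch",
    "outcome",
    "probability",
    "mean_peak_dff",
    "mean_duration_ms",
    "n_trials",
    "n_event_trials",
]


@dataclass(frozen=True)
class EpochDefinition:
    """A named analysis window anchored to a trial event."""

    name: str
    anchor: str                 # "stimulus_onset" | "reward_delivery"
    window: tuple[float, float]  # [start, end) seconds relative to anchor

    def __post_init__(self) -> None:
        if self.anchor not in ("stimulus_onset", "reward_delivery"):
            raise PomtraceError(f"unknown anchor {self.anchor!r}")
        if self.window[1] <= self.window[0]:
            raise PomtraceError(f"empty window for epoch {self.name!r}")


def canonical_epochs(split_stimulus: bool = False) -> list[EpochDefinition]:
    """The canonical epoch set (optionally splitting stimulus/response)."""
    defs = [EpochDefinition("spontaneous", "stimulus_onset", (-2.0, -1.0))]
    if split_stimulus:
        defs += [
            EpochDefinition("stimulus", "stimulus_onset", (0.0, 0.5)),
            EpochDefinition("response", "stimulus_onset", (0.5, 1.0)),
        ]
    else:
        defs.append(EpochDefinition("response", "stimulus_onset", (0.0, 1.0)))
    defs.append(EpochDefinition("reward", "reward_delivery", (0.0, 1.0)))
    return defs


def assign_epoch_windows(
    trials: pd.DataFrame, defs: list[EpochDefinition] | None = None
) -> pd.DataFrame:
    """Resolve epoch definitions to per-trial trial-relative windows.

    Returns a tidy frame (trial_id, epoch, win_start, win_end) in
    seconds relative to trial start.  Reward windows are emitted only
    for trials with a recorded reward delivery (never zero-filled).
    """
    if defs is None:
        defs = canonical_epochs()
    rows = []
    for trial in trials.itertuples():
        stim_rel = (
            trial.t_stimulus - trial.t_start
            if np.isfinite(trial.t_stimulus)
            else STIM_ONSET_S  # virtual stimulus time on catch trials
        )
        reward_rel = (
            trial.t_reward - trial.t_start if np.isfinite(trial.t_reward) else None
        )
        for d in defs:
            if d.anchor == "stimulus_onset":
                anchor = stim_rel
            else:
                if reward_rel is None:
                    continue  # unrewarded trial: window omitted
                anchor = reward_rel
            rows.append(
                {
                    "trial_id": int(trial.trial_id),
                    "epoch": d.name,
                    "win_start": anchor + d.window[0],
                    "win_end": anchor + d.window[1],
                }
            )
    return pd.DataFrame(rows)


def _event_trial_flags(events: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Events joined to epoch windows, keeping only in-window onsets."""
    if events.empty or windows.empty:
        return pd.DataFrame(columns=["roi_id", "trial_id", "epoch", "onset_s", "peak_dff", "duration_ms"])
    merged = events.merge(windows, on="trial_id")
    inside = (merged["onset_s"] >= merged["win_start"]) & (merged["onset_s"] < merged["win_end"])
    return merged.loc[inside, ["roi_id", "trial_id", "epoch", "onset_s", "peak_dff", "duration_ms"]]


def event_probability(
    events: pd.DataFrame,
    windows: pd.DataFrame,
    trials: pd.DataFrame,
    active_rois: list[str],
) -> pd.DataFrame:
    """Per-trial transient probability per ROI, epoch, and outcome class.

    A trial is an event-trial for an epoch when the ROI has at least
    one event onset inside the trial's window; the probability is
    event-trials over eligible trials (trials of the outcome class that
    carry the window).  Zero eligible trials yield a missing statistic,
    never 0.
    """
    outcome_by_id = trials.set_index("trial_id")["outcome"]
    win = windows.copy()
    win["outcome"] = outcome_by_id.loc[win["trial_id"]].to_numpy()
    eligible = (
        win.groupby(["epoch", "outcome"])["trial_id"].nunique().rename("n_trials").reset_index()
    )

    flagged = _event_trial_flags(events, windows)
    flagged = flagged[flagged["roi_id"].isin(active_rois)]
    flagged = flagged.merge(
        outcome_by_id.rename("outcome"), left_on="trial_id", right_index=True
    )
    ev_counts = (
        flagged.groupby(["roi_id", "epoch", "outcome"])["trial_id"]
        .nunique()
        .rename("n_event_trials")
        .reset_index()
    )

    grid = (
        pd.MultiIndex.from_product(
            [active_rois, eligible["epoch"].unique(), eligible["outcome"].unique()],
            names=["roi_id", "epoch", "outcome"],
        )
        .to_frame(index=False)
        .merge(eligible, on=["epoch", "outcome"], how="inner")
        .merge(ev_counts, on=["roi_id", "epoch", "outcome"], how="left")
    )
    grid["n_event_trials"] = grid["n_event_trials"].fillna(0).astype(int)
    grid["probability"] = np.where(
        grid["n_trials"] > 0, grid["n_event_trials"] / grid["n_trials"], np.nan
    )
    return grid.sort_values(["roi_id", "epoch", "outcome"]).reset_index(drop=True)


def evoked_amplitude_stats(
    events: pd.DataFrame,
    windows: pd.DataFrame,
    trials: pd.DataFrame,
    active_rois: list[str] | None = None,
) -> pd.DataFrame:
    """Mean evoked peak amplitude (dF/F) and duration (ms) per ROI/epoch/outcome.

    Uses the first event of each trial-epoch; ROIs without any event in
    an epoch are excluded from that epoch's statistic (no row emitted).
    """
    flagged = _event_trial_flags(events, windows)
    if active_rois is not None:
        flagged = flagged[flagged["roi_id"].isin(active_rois)]
    if flagged.empty:
        return pd.DataFrame(
            columns=["roi_id", "epoch", "outcome", "mean_peak_dff", "mean_duration_ms", "n_event_trials"]
        )
    outcome_by_id = trials.set_index("trial_id")["outcome"]
    flagged = flagged.merge(outcome_by_id.rename("outcome"), left_on="trial_id", right_index=True)
    first = (
        flagged.sort_values("onset_s")
        .groupby(["roi_id", "epoch", "outcome", "trial_id"], as_index=False)
        .first()
    )
    stats = (
        first.groupby(["roi_id", "epoch", "outcome"])
        .agg(
            mean_peak_dff=("peak_dff", "mean"),
            mean_duration_ms=("duration_ms", "mean"),
            n_event_trials=("trial_id", "nunique"),
        )
        .reset_index()
    )
    return stats.sort_values(["roi_id", "epoch", "outcome"]).reset_index(drop=True)


def compute_epoch_stats(
    events: pd.DataFrame,
    windows: pd.DataFrame,
    trials: pd.DataFrame,
    active_rois: list[str],
) -> pd.DataFrame:
    """Combined tidy per-ROI/epoch/outcome statistics table."""
    prob = event_probability(events, windows, trials, active_rois)
    amp = evoked_amplitude_stats(events, windows, trials, active_rois)
    merged = prob.merge(
        amp.drop(columns="n_event_trials"), on=["roi_id", "epoch", "outcome"], how="left"
    )
    return merged[EPOCH_STAT_COLUMNS]


def trial_relative_epoch_windows(
    defs: list[EpochDefinition] | None = None,
    stim_rel_s: float = STIM_ONSET_S,
    reward_rel_s: float = REWARD_ONSET_S,
) -> dict[str, tuple[float, float]]:
    """Canonical epoch windows in seconds relative to trial start."""
    if defs is None:
        defs = canonical_epochs()
    out = {}
    for d in defs:
        anchor = stim_rel_s if d.anchor == "stimulus_onset" else reward_rel_s
        out[d.name] = (anchor + d.window[0], anchor + d.window[1])
    return out


def categorize_axons_by_peak(
    avg_traces: np.ndarray,
    sample_times: np.ndarray,
    roi_ids: list[str],
    windows: dict[str, tuple[float, float]] | None = None,
) -> pd.Series:
    """Label each ROI by the epoch containing the peak of its averaged trace.

    The label is the epoch whose window contains the global maximum of
    the (typically HIT-trial-averaged) dF/F trace; the first maximum
    wins on ties, which resolves toward the earlier epoch.  Flat or
    all-missing traces (and peaks outside every window) are labeled
    ``"none"``.
    """
    if windows is None:
        windows = trial_relative_epoch_windows()
    labels = {}
    for i, roi_id in enumerate(roi_ids):
        x = avg_traces[i]
        finite = np.isfinite(x)
        if not finite.any() or np.nanmax(x) == np.nanmin(x):
            labels[roi_id] = "none"
            continue
        t_peak = sample_times[np.nanargmax(x)]
        label = "none"
        for name, (lo, hi) in windows.items():
            if lo <= t_peak < hi:
                label = name
                break
        labels[roi_id] = label
    return pd.Series(labels, name="peak_epoch").rename_axis("roi_id")


def mass_average(
    dff: np.ndarray, trial_mask: np.ndarray | None = None, roi_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Population mass average of trial-aligned traces.

    Averages over trials within each ROI, then over ROIs (whether or
    not they responded); the SEM is across ROIs.  ``dff`` is a
    (rois, trials, samples) tensor; masks select subsets.
    """
    sel = dff
    if trial_mask is not None:
        sel = sel[:, np.asarray(trial_mask), :]
    if roi_mask is not None:
        sel = sel[np.asarray(roi_mask)]
    if sel.size == 0:
        raise PomtraceError("mass_average needs at least one ROI and one trial")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        per_roi = np.nanmean(sel, axis=1)          # (rois, samples)
        mean = np.nanmean(per_roi, axis=0)
        n = np.isfinite(per_roi).sum(axis=0)
        sem = np.nanstd(per_roi, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    return mean, sem


def display_matrix(
    avg_traces: np.ndarray, sample_times: np.ndarray, roi_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Rows normalized to their maximum and sorted by peak time.

    Rows with a non-positive maximum carry no displayable response and
    are dropped with a log entry.  Equal peak times keep a stable order
    by ROI id.
    """
    rows, order_keys = [], []
    for i, roi_id in enumerate(roi_ids):
        x = avg_traces[i]
        peak = np.nanmax(x) if np.isfinite(x).any() else np.nan
        if not np.isfinite(peak) or peak <= 0:
            logger.info("display_matrix: dropping ROI %s (non-positive max)", roi_id)
            continue
        rows.append(x / peak)
        order_keys.append((float(sample_times[np.nanargmax(x)]), roi_id, len(rows) - 1))
    if not rows:
        raise PomtraceError("no ROI has a positive maximum; nothing to display")
    order_keys.sort(key=lambda k: (k[0], k[1]))
    matrix = np.asarray([rows[k[2]] for k in order_keys])
    ordered_ids = [k[1] for k in order_keys]
    return matrix, ordered_ids
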