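"""End-to-end session analysis: traces in, epoch statistics out.

Chains the standard stages — trial segmentation, rolling-median F0,
dF/F, transient detection, duplicate-ROI removal, active-axon
filtering, epoch windows, per-epoch statistics, and behavioral metrics
— with the default parameters used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior as bh
from . import epochs as ep
from . import events as ev
from . import fluorescence as fl
from .errors import PomtraceError


@dataclass
class SessionResult:
    """All intermediate and final products of one session's analysis."""

    trials: pd.DataFrame
    tensor: fl.TrialTensor
    baseline: fl.BaselineSeries
    dff: fl.TrialAlignedTraces
    events: pd.DataFrame          # events of kept (non-duplicate) ROIs
    all_events: pd.DataFrame      # events before duplicate removal
    dedup: ev.DedupResult | None
    active_rois: list[str]
    windows: pd.DataFrame
    epoch_stats: pd.DataFrame
    metrics: bh.BehaviorMetrics | None


def analyze_session(
    traces: fl.TraceMatrix,
    trials: pd.DataFrame,
    *,
    rolling_window: int = 5,
    threshold_k: float = 2.0,
    min_duration_ms: float = 200.0,
    dedup: bool = True,
    agreement_threshold: float = 0.95,
    onset_tolerance_frames: int = 2,
    epoch_defs: list[ep.EpochDefinition] | None = None,
) -> SessionResult:
    """Run the full trace-to-statistics pipeline on one session."""
    tensor = fl.segment_trials(traces, trials)
    kept_trials = trials[trials["trial_id"].isin(tensor.trial_ids)].reset_index(drop=True)
    baseline = fl.compute_f0(tensor, rolling_window=rolling_window)
    dff = fl.compute_dff(tensor, baseline)
    all_events = ev.detect_events(
        dff, baseline, threshold_k=threshold_k, min_duration_ms=min_duration_ms
    )

    dedup_result = None
    kept_events = all_events
    roi_ids = list(traces.roi_ids)
    if dedup and len(roi_ids) >= 2 and len(tensor.trial_ids) >= 2:
        dedup_result = ev.deduplicate_rois(
            all_events,
            tensor.trial_ids,
            roi_ids,
            agreement_threshold=agreement_threshold,
            onset_tolerance_frames=onset_tolerance_frames,
            frame_rate=traces.frame_rate,
        )
        roi_ids = dedup_result.kept_roi_ids
        kept_events = all_events[all_events["roi_id"].isin(roi_ids)].reset_index(drop=True)

    active = ev.flag_active_rois(kept_events, roi_ids)
    windows = ep.assign_epoch_windows(kept_trials, epoch_defs)
    stats = ep.compute_epoch_stats(kept_events, windows, kept_trials, active)

    metrics = None
    try:
        metrics = bh.session_metrics(kept_trials)
    except PomtraceError:
        pass  # e.g. a session without catch trials has no d'
    return SessionResult(
        kept_trials,
        tensor,
        baseline,
        dff,
        kept_events,
        all_events,
        dedup_result,
        active,
        windows,
        stats,
        metrics,
    )


def mean_epoch_probabilities(epoch_stats: pd.DataFrame, outcome: str = "HIT") -> pd.Series:
    """Across-ROI mean event probability per epoch for one outcome class."""
    sel = epoch_stats[epoch_stats["outcome"] == outcome]
    return sel.groupby("epoch")["probability"].mean()


def mean_epoch_amplitudes(epoch_stats: pd.DataFrame, outcome: str = "HIT") -> pd.Series:
    """Across-ROI mean evoked peak amplitude (dF/F) per epoch."""
    sel = epoch_stats[(epoch_stats["outcome"] == outcome) & epoch_stats["mean_peak_dff"].notna()]
    return sel.groupby("epoch")["mean_peak_dff"].mean()


def paired_outcome_contrast(
    epoch_stats: pd.DataFrame, epoch: str = "response", a: str = "HIT", b: str = "MISS"
) -> float:
    """Mean per-ROI probability difference between two outcome classes.

    Pairs each ROI's probabilities in the two classes (dropping ROIs
    missing either) and returns the mean difference — positive when
    class ``a`` evokes transients more reliably.
    """
    sel = epoch_stats[epoch_stats["epoch"] == epoch]
    wide = sel.pivot(index="roi_id", columns="outcome", values="probability")
    if a not in wide or b not in wide:
        raise PomtraceError(f"missing outcome class {a!r} or {b!r} in epoch stats")
    paired = wide[[a, b]].dropna()
    if paired.empty:
        raise PomtraceError("no ROI has both outcome classes defined")
    return float((paired[a] - paired[b]).mean())


def per_trial_activity(events: pd.DataFrame, trial_ids: np.ndarray, n_rois: int) -> pd.Series:
    """Fraction of ROIs with at least one event, per trial."""
    counts = events.groupby("trial_id")["roi_id"].nunique()
    out = pd.Series(0.0, index=pd.Index(np.asarray(trial_ids), name="trial_id"))
    out.loc[counts.index.intersection(out.index)] = counts / max(n_rois, 1)
    return out.rename("active_fraction")
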