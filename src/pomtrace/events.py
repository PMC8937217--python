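"""Ca2+ transient detection and axon deduplication.

A transient is detected wherever the dF/F trace exceeds twice the
ROI's baseline standard deviation (the raw-fluorescence criterion
F0 + 2*SD expressed in dF/F units, i.e. 2*SD/F0) for strictly longer
than 200 ms.  Event onset is the first suprathreshold sample, offset
the first sample back below threshold, peak amplitude the local maximum
between them, and duration the onset-offset interval.  At 30 Hz the
duration rule means at least 7 consecutive suprathreshold samples: a
6-sample run lasts exactly 200 ms and is rejected.

ROIs drawn over branches or boutons of the same axon report the same
underlying activity.  Pairs of ROIs whose events are temporally
coincident (onsets within a small tolerance, or both silent) in more
than 95% of trials are presumed to belong to one axon; connected
components of such pairs form duplicate groups and only the member with
the highest mean event amplitude (the best-SNR branch) is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import PomtraceError
from .fluorescence import BaselineSeries, TrialAlignedTraces

EVENT_COLUMNS = ["roi_id", "trial_id", "onset_s", "offset_s", "peak_dff", "duration_ms"]


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "roi_id": pd.Series(dtype=str),
            "trial_id": pd.Series(dtype=int),
            "onset_s": pd.Series(dtype=float),
            "offset_s": pd.Series(dtype=float),
            "peak_dff": pd.Series(dtype=float),
            "duration_ms": pd.Series(dtype=float),
        }
    )


def detect_events(
    dff: TrialAlignedTraces,
    baseline: BaselineSeries,
    threshold_k: float = 2.0,
    min_duration_ms: float = 200.0,
) -> pd.DataFrame:
    """Detect suprathreshold transients in trial-aligned dF/F traces.

    The per-ROI, per-trial threshold is
    ``threshold_k * baseline_sd / F0(trial)`` in dF/F units.  Maximal
    contiguous runs of samples strictly above threshold become events if
    they last strictly longer than ``min_duration_ms``; missing (NaN)
    samples split runs at the gap.  Onset and offset times are
    trial-relative seconds; a run still above threshold at the end of
    the trial window is closed one sample past the last one.
    """
    n_rois, n_trials, n_samples = dff.dff.shape
    dt = 1.0 / dff.frame_rate
    times = dff.sample_times
    records: list[tuple] = []
    for r in range(n_rois):
        sd = baseline.baseline_sd[r]
        if not np.isfinite(sd):
            continue
        roi_id = dff.roi_ids[r]
        for t in range(n_trials):
            f0 = baseline.f0[r, t]
            if not np.isfinite(f0) or f0 <= 0:
                continue
            thr = threshold_k * sd / f0
            x = dff.dff[r, t]
            above = np.isfinite(x) & (x > thr)
            if not above.any():
                continue
            edges = np.diff(above.astype(np.int8), prepend=0, append=0)
            starts = np.flatnonzero(edges == 1)
            ends = np.flatnonzero(edges == -1)
            for i0, i1 in zip(starts, ends):
                onset = times[i0]
                offset = times[i1] if i1 < n_samples else times[-1] + dt
                # duration from the sample count, so the strict 200 ms
                # boundary (6 samples at 30 Hz) is decided exactly
                duration_ms = (i1 - i0) / dff.frame_rate * 1000.0
                if duration_ms <= min_duration_ms:
                    continue
                peak = float(np.max(x[i0:i1]))
                records.append(
                    (roi_id, int(dff.trial_ids[t]), float(onset), float(offset), peak, duration_ms)
                )
    if not records:
        return _empty_events()
    return pd.DataFrame(records, columns=EVENT_COLUMNS)


def flag_active_rois(events: pd.DataFrame, roi_ids: list[str]) -> list[str]:
    """ROIs with at least one detected transient anywhere in the session.

    Only these "active axons" enter probability analyses; amplitude and
    duration statistics additionally require an event in the analyzed
    epoch (enforced downstream).
    """
    active = set(events["roi_id"].unique())
    return [roi_id for roi_id in roi_ids if roi_id in active]


@dataclass
class DedupResult:
    """Outcome of duplicate-ROI removal."""

    kept_roi_ids: list[str]
    duplicate_groups: list[list[str]]
    pairwise_agreement: pd.DataFrame

    @property
    def removed_roi_ids(self) -> list[str]:
        kept = set(self.kept_roi_ids)
        return [r for g in self.duplicate_groups for r in g if r not in kept]


def deduplicate_rois(
    events: pd.DataFrame,
    trial_ids: np.ndarray,
    roi_ids: list[str],
    agreement_threshold: float = 0.95,
    onset_tolerance_frames: int = 2,
    frame_rate: float = 30.0,
) -> DedupResult:
    """Group ROIs with temporally coincident events and keep one per group.

    Per ROI pair and trial, agreement is 1 when both ROIs have an event
    with onsets within ``onset_tolerance_frames`` frames of each other,
    or both have no event; otherwise 0.  Pairs whose mean agreement over
    trials exceeds ``agreement_threshold`` are linked; connected
    components form duplicate groups and the member with the highest
    mean event peak amplitude survives.  Single-trial sessions skip
    deduplication with a warning (the trial fraction is not robust).
    """
    if len(roi_ids) < 2:
        raise PomtraceError("deduplication needs at least 2 ROIs")
    trial_ids = np.asarray(trial_ids)
    n_trials = len(trial_ids)
    n_rois = len(roi_ids)
    agreement = pd.DataFrame(np.eye(n_rois), index=roi_ids, columns=roi_ids)
    if n_trials < 2:
        warnings.warn("single-trial session: deduplication skipped", stacklevel=2)
        return DedupResult(list(roi_ids), [], agreement)

    roi_index = {roi_id: i for i, roi_id in enumerate(roi_ids)}
    trial_index = {int(t): j for j, t in enumerate(trial_ids)}

    # Onsets binned to the frame grid; a pair of onsets matches when the
    # bins are within the tolerance, realized by dilating one side.
    if len(events):
        bins = np.floor(events["onset_s"].to_numpy() * frame_rate + 0.5).astype(int)
        n_bins = int(bins.max()) + 1
    else:
        n_bins = 1
    onset_grid = np.zeros((n_rois, n_trials, n_bins), dtype=bool)
    if len(events):
        for roi, trial, b in zip(
            events["roi_id"].to_numpy(), events["trial_id"].to_numpy(), bins
        ):
            r = roi_index.get(roi)
            t = trial_index.get(int(trial))
            if r is None or t is None:
                continue
            onset_grid[r, t, b] = True
    dilated = onset_grid.copy()
    for off in range(1, onset_tolerance_frames + 1):
        dilated[:, :, off:] |= onset_grid[:, :, :-off]
        dilated[:, :, :-off] |= onset_grid[:, :, off:]

    has_event = onset_grid.any(axis=2)  # (rois, trials)
    agree_counts = np.zeros((n_rois, n_rois), dtype=np.float64)
    none_f = (~has_event).astype(np.float32)
    agree_counts += none_f @ none_f.T  # both silent
    for t in range(n_trials):
        match = (dilated[:, t, :].astype(np.float32) @ onset_grid[:, t, :].astype(np.float32).T) > 0
        agree_counts += match
    frac = agree_counts / n_trials
    np.fill_diagonal(frac, 1.0)
    agreement.iloc[:, :] = frac

    linked = (frac > agreement_threshold) & ~np.eye(n_rois, dtype=bool)
    n_comp, labels = connected_components(csr_matrix(linked), directed=False)

    mean_peak = events.groupby("roi_id")["peak_dff"].mean() if len(events) else pd.Series(dtype=float)
    groups: list[list[str]] = []
    kept: list[str] = []
    for comp in range(n_comp):
        members = [roi_ids[i] for i in np.flatnonzero(labels == comp)]
        if len(members) == 1:
            kept.append(members[0])
            continue
        groups.append(members)
        peaks = np.array([mean_peak.get(m, -np.inf) for m in members])
        kept.append(members[int(np.argmax(peaks))])
    kept = [r for r in roi_ids if r in set(kept)]  # stable order
    return DedupResult(kept, groups, agreement)
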