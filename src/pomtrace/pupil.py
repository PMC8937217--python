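"""Trial-aligned pupillometry.

The pupil diameter trace of a session is split into 11-s trial windows
(4 s before trial start to 7 s after).  Per behavioral outcome class,
the aligned traces are averaged and the peak (local maximum of the
average) is measured in three named windows: the pre-trial *baseline*
(-4 to 0 s relative to trial start), the *pre-tactile* window (-3 to
0 s relative to stimulus onset) and the *post-tactile* window (0 to
+4 s relative to stimulus onset).  Samples flagged as artifacts
(eyelid closures) are excluded; a trial is dropped entirely when more
than 20% of any analysis window is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import STIM_ONSET_S
from .errors import PomtraceError

#: Aligned trial span in seconds relative to trial start (11 s total).
TRIAL_SPAN_S = (-4.0, 7.0)

#: Analysis windows in seconds relative to trial start (half-open).
#: pre_tac and post_tac are anchored to stimulus onset (trial start + 3 s).
PUPIL_WINDOWS = {
    "baseline": (-4.0, 0.0),
    "pre_tac": (STIM_ONSET_S - 3.0, STIM_ONSET_S),
    "post_tac": (STIM_ONSET_S, STIM_ONSET_S + 4.0),
}


@dataclass
class PupilTrace:
    """Timestamped pupil diameter with per-sample artifact flags."""

    times: np.ndarray          # seconds from session start
    diameter: np.ndarray       # mm
    artifact: np.ndarray       # bool per sample

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.artifact is None:
            self.artifact = np.zeros(len(self.times), dtype=bool)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        if not (len(self.times) == len(self.diameter) == len(self.artifact)):
            raise PomtraceError("pupil trace arrays must have equal length")

    @property
    def rate(self) -> float:
        if len(self.times) < 2:
            raise PomtraceError("pupil trace too short to infer a sample rate")
        return 1.0 / float(np.median(np.diff(self.times)))


def align_pupil_trials(
    trace: PupilTrace, trials: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Slice the session trace into 11-s windows aligned to trial starts.

    Returns ``(diam, flags, rel_times, trial_ids)`` where ``diam`` and
    ``flags`` are (n_kept_trials, n_samples) arrays; trials not fully
    covered by the trace are silently skipped.
    """
    rate = trace.rate
    dt = 1.0 / rate
    n_samples = int(round((TRIAL_SPAN_S[1] - TRIAL_SPAN_S[0]) * rate))
    rows, frows, kept = [], [], []
    for trial in trials.itertuples():
        start_t = trial.t_start + TRIAL_SPAN_S[0]
        idx = int(round((start_t - trace.times[0]) * rate))
        if idx < 0 or idx + n_samples > len(trace.times):
            continue
        rows.append(trace.diameter[idx : idx + n_samples])
        frows.append(trace.artifact[idx : idx + n_samples])
        kept.append(int(trial.trial_id))
    if not rows:
        raise PomtraceError("no trial window is covered by the pupil trace")
    rel_times = TRIAL_SPAN_S[0] + np.arange(n_samples) * dt
    return np.asarray(rows), np.asarray(frows), rel_times, np.asarray(kept)


def pupil_epoch_peaks(
    trace: PupilTrace,
    trials: pd.DataFrame,
    max_flagged_frac: float = 0.2,
) -> pd.DataFrame:
    """Peak diameter of the trial-averaged pupil response per window and outcome.

    For each outcome class the per-trial aligned traces are averaged
    (artifact samples excluded) and the maximum of the average inside
    each of the baseline / pre-tactile / post-tactile windows is
    returned in mm.  Trials with more than ``max_flagged_frac`` of any
    window flagged are dropped; an error is raised if no trial survives.
    """
    diam, flags, rel_times, kept_ids = align_pupil_trials(trace, trials)
    outcome_by_id = trials.set_index("trial_id")["outcome"]
    window_masks = {
        name: (rel_times >= lo) & (rel_times < hi) for name, (lo, hi) in PUPIL_WINDOWS.items()
    }
    trial_ok = np.ones(len(kept_ids), dtype=bool)
    for mask in window_masks.values():
        frac = flags[:, mask].mean(axis=1)
        trial_ok &= frac <= max_flagged_frac
    if not trial_ok.any():
        raise PomtraceError("all trials exceed the artifact budget; no pupil data left")

    clean = np.where(flags, np.nan, diam)
    records = []
    for outcome in pd.unique(outcome_by_id.loc[kept_ids]):
        sel = trial_ok & (outcome_by_id.loc[kept_ids].to_numpy() == outcome)
        if not sel.any():
            continue
        avg = np.nanmean(clean[sel], axis=0)
        row = {"outcome": outcome, "n_trials": int(sel.sum())}
        for name, mask in window_masks.items():
            row[name] = float(np.nanmax(avg[mask]))
        records.append(row)
    return pd.DataFrame(records).set_index("outcome")
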