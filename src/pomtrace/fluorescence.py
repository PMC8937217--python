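"""ROI trace extraction, trial alignment, baseline F0, and dF/F.

The baseline fluorescence F0 of each ROI is estimated per trial: first
the average pre-stimulus fluorescence (the 60 frames / 2 s before
stimulus onset) of each trial is taken, then a centered rolling median
of these per-trial means (window truncated at session edges) gives
F0(trial).  Relative fluorescence change is dF/F = (F - F0) / F0.
The baseline standard deviation used by event detection is pooled over
every trial's pre-stimulus raw samples of the ROI, giving a stable
noise estimate in raw-fluorescence units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import STIM_ONSET_S, TRIAL_WINDOW_S
from .errors import AlignmentError, GeometryError, PomtraceError
from .registration import FrameStack


@dataclass
class RoiMaskSet:
    """Pixel masks of axonal ROIs, keyed by ROI id.

    ``pixels`` maps each ROI id to a ``(rows, cols)`` pair of 0-based
    coordinate arrays.  Every ROI must be nonempty and ids unique.
    """

    pixels: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for roi_id, (rows, cols) in self.pixels.items():
            rows = np.asarray(rows, dtype=int)
            cols = np.asarray(cols, dtype=int)
            if rows.size == 0 or rows.size != cols.size:
                raise GeometryError(f"ROI {roi_id!r} is empty or malformed")
            clean[str(roi_id)] = (rows, cols)
        self.pixels = clean

    @property
    def roi_ids(self) -> list[str]:
        return list(self.pixels)

    def __len__(self) -> int:
        return len(self.pixels)

    def check_within(self, shape: tuple[int, int]) -> None:
        for roi_id, (rows, cols) in self.pixels.items():
            if rows.min() < 0 or cols.min() < 0 or rows.max() >= shape[0] or cols.max() >= shape[1]:
                raise GeometryError(f"ROI {roi_id!r} falls outside the {shape} field of view")

    def centroids(self) -> dict[str, tuple[float, float]]:
        return {
            roi_id: (float(rows.mean()), float(cols.mean()))
            for roi_id, (rows, cols) in self.pixels.items()
        }

    def to_label_image(self, shape: tuple[int, int]) -> np.ndarray:
        """Render the masks as a 16-bit label image (labels follow id order)."""
        self.check_within(shape)
        img = np.zeros(shape, dtype=np.uint16)
        for label, (roi_id, (rows, cols)) in enumerate(self.pixels.items(), start=1):
            img[rows, cols] = label
        return img

    @classmethod
    def from_label_image(cls, label_img: np.ndarray, roi_ids: list[str] | None = None) -> "RoiMaskSet":
        labels = np.unique(label_img)
        labels = labels[labels > 0]
        if roi_ids is None:
            roi_ids = [f"roi{int(l):03d}" for l in labels]
        if len(roi_ids) != len(labels):
            raise GeometryError("roi_ids length must match number of labels")
        pixels = {}
        for roi_id, label in zip(roi_ids, labels):
            rows, cols = np.nonzero(label_img == label)
            pixels[roi_id] = (rows, cols)
        return cls(pixels)


@dataclass
class TraceMatrix:
    """ROI x frame raw fluorescence with a frame clock."""

    values: np.ndarray          # (n_rois, n_frames), NaN = missing sample
    frame_times: np.ndarray    # seconds from session start
    roi_ids: list[str]
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.ndim != 2:
            raise PomtraceError("trace values must be 2-D (roi x frame)")
        if self.values.shape != (len(self.roi_ids), len(self.frame_times)):
            raise PomtraceError("trace dimensions inconsistent with roi_ids / frame_times")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class TrialTensor:
    """Raw fluorescence sliced into per-trial windows on a common grid."""

    values: np.ndarray         # (n_rois, n_trials, n_samples)
    sample_times: np.ndarray   # seconds, trial-relative (0 = trial start)
    trial_ids: np.ndarray
    roi_ids: list[str]
    frame_rate: float
    dropped_trials: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class BaselineSeries:
    """Per-ROI, per-trial baseline F0 and pooled baseline noise."""

    f0: np.ndarray             # (n_rois, n_trials)
    baseline_sd: np.ndarray    # (n_rois,), raw-fluorescence units
    baseline_means: np.ndarray  # (n_rois, n_trials) per-trial pre-stimulus means
    rolling_window: int
    roi_ids: list[str]
    trial_ids: np.ndarray


@dataclass
class TrialAlignedTraces:
    """ROI x trial x sample dF/F tensor on the session's common grid."""

    dff: np.ndarray
    sample_times: np.ndarray
    trial_ids: np.ndarray
    roi_ids: list[str]
    frame_rate: float
    excluded_rois: list[tuple[str, str]] = field(default_factory=list)

    def trial_average(self, trial_mask: np.ndarray | None = None) -> np.ndarray:
        """Mean dF/F over (a subset of) trials, per ROI: (n_rois, n_samples)."""
        sel = self.dff if trial_mask is None else self.dff[:, np.asarray(trial_mask), :]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(sel, axis=1)


def extract_traces(
    stack: FrameStack,
    masks: RoiMaskSet,
    flagged_frames: np.ndarray | None = None,
) -> TraceMatrix:
    """Mean-intensity ROI traces from a (motion-corrected) frame stack.

    Samples from frames flagged by registration are set to NaN so that
    downstream statistics skip them.
    """
    masks.check_within(stack.shape)
    values = np.empty((len(masks), stack.n_frames), dtype=float)
    for i, roi_id in enumerate(masks.roi_ids):
        rows, cols = masks.pixels[roi_id]
        values[i] = stack.frames[:, rows, cols].mean(axis=1)
    if flagged_frames is not None:
        flagged_frames = np.asarray(flagged_frames, dtype=bool)
        values[:, flagged_frames] = np.nan
    return TraceMatrix(values, stack.frame_times, masks.roi_ids, stack.frame_rate)


def segment_trials(
    traces: TraceMatrix,
    trials: pd.DataFrame,
    window_s: float = TRIAL_WINDOW_S,
) -> TrialTensor:
    """Slice ROI traces into per-trial windows [t_start, t_start + window_s).

    Every kept trial is sampled on the identical trial-relative grid.
    Trials that start off the frame grid or are not fully covered by the
    recording are dropped with a logged reason; if no trial survives an
    :class:`AlignmentError` is raised.
    """
    rate = traces.frame_rate
    n_samples = int(round(window_s * rate))
    t0 = traces.frame_times[0]
    n_frames = traces.values.shape[1]

    kept_rows = []
    kept_ids = []
    dropped: list[tuple[int, str]] = []
    for trial in trials.itertuples():
        start_idx = int(round((trial.t_start - t0) * rate))
        if start_idx < 0 or start_idx + n_samples > n_frames:
            dropped.append((int(trial.trial_id), "trial window not fully covered by recording"))
            continue
        if abs(traces.frame_times[start_idx] - trial.t_start) > 0.51 / rate:
            dropped.append((int(trial.trial_id), "trial start off the frame grid"))
            continue
        kept_rows.append(traces.values[:, start_idx : start_idx + n_samples])
        kept_ids.append(int(trial.trial_id))
    if not kept_rows:
        raise AlignmentError("no trial is fully covered by the recording")
    values = np.stack(kept_rows, axis=1)  # (rois, trials, samples)
    sample_times = np.arange(n_samples) / rate
    return TrialTensor(
        values, sample_times, np.asarray(kept_ids), traces.roi_ids, rate, dropped
    )


def compute_f0(
    tensor: TrialTensor,
    rolling_window: int = 5,
    stim_onset_s: float = STIM_ONSET_S,
    baseline_window_s: float = 2.0,
    min_baseline_frac: float = 0.8,
) -> BaselineSeries:
    """Rolling-median baseline F0 and pooled baseline SD per ROI.

    Per trial, the mean of the pre-stimulus samples (the 2 s / 60 frames
    at 30 Hz preceding stimulus onset) is taken; F0(trial) is the
    centered rolling median of these means over ``rolling_window``
    trials, truncated at the session edges.  A trial whose pre-stimulus
    window has too few valid samples (fewer than ``min_baseline_frac``
    of the expected count) contributes no baseline mean and is skipped
    by the rolling median.
    """
    if tensor.values.shape[1] < 1:
        raise PomtraceError("compute_f0 requires at least one trial")
    mask = (tensor.sample_times >= stim_onset_s - baseline_window_s) & (
        tensor.sample_times < stim_onset_s
    )
    n_expected = int(round(baseline_window_s * tensor.frame_rate))
    base = tensor.values[:, :, mask]  # (rois, trials, baseline samples)
    finite = np.isfinite(base)
    counts = finite.sum(axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(base, axis=2)
        means[counts < min_baseline_frac * n_expected] = np.nan
        if base.shape[2] < n_expected:  # grid itself too short
            means[:] = np.nan
        sd = np.nanstd(base.reshape(base.shape[0], -1), axis=1, ddof=1)

    n_rois, n_trials = means.shape
    half = rolling_window // 2
    f0 = np.full_like(means, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for t in range(n_trials):
            lo, hi = max(0, t - half), min(n_trials, t + half + 1)
            f0[:, t] = np.nanmedian(means[:, lo:hi], axis=1)
    return BaselineSeries(f0, sd, means, rolling_window, tensor.roi_ids, tensor.trial_ids)


def compute_dff(tensor: TrialTensor, baseline: BaselineSeries) -> TrialAlignedTraces:
    """Elementwise dF/F = (F - F0(trial)) / F0(trial).

    ROIs whose F0 is non-positive on any trial are excluded (their rows
    are NaN) with a logged reason; individual trials with missing F0
    yield NaN samples for that ROI/trial only.
    """
    f0 = baseline.f0
    excluded: list[tuple[str, str]] = []
    dff = np.full_like(tensor.values, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        valid_trial = np.isfinite(f0) & (f0 > 0)
        dff = (tensor.values - f0[:, :, None]) / f0[:, :, None]
        dff[~valid_trial, :] = np.nan
    bad_roi = np.any(np.isfinite(f0) & (f0 <= 0), axis=1)
    for i, roi_id in enumerate(tensor.roi_ids):
        if bad_roi[i]:
            dff[i] = np.nan
            excluded.append((roi_id, "non-positive baseline F0"))
    return TrialAlignedTraces(
        dff, tensor.sample_times, tensor.trial_ids, tensor.roi_ids, tensor.frame_rate, excluded
    )
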