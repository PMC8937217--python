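"""Synthetic go/no-go imaging sessions with known ground truth.

Generates complete sessions — trial tables, axonal fluorescence traces,
optional rendered frame stacks, and pupil traces — whose every injected
quantity is recorded, so each downstream stage of the pipeline can be
validated without any recorded data.

The generative model per axon, trial, and epoch: with the configured
probability, one Ca2+ transient is injected with its onset uniform in
the epoch window and a lognormal dF/F amplitude; the impulse train is
convolved with a difference-of-exponentials kernel (GCaMP6f-like rise
and decay, normalized to unit peak on the sample grid) and embedded in
raw fluorescence as ``F0 * (1 + dF/F) + drift + noise``, where the
drift is a slow sinusoid and the noise is white.  Branch ROIs of one
axon share the parent's event train exactly and differ only in noise
and drift phase.  Trial starts are snapped to the 1/15 s grid, the
common multiple of the 30 Hz imaging and 15 Hz pupil clocks, so that
trial-aligned sample grids are identical across trials.

Behavioral outcomes are sampled from configurable HIT/FA rates rather
than from a behavioral model: outcomes are inputs to, not outputs of,
the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from .config import (
    CANONICAL_EPOCH_NAMES,
    ITI_RANGE_S,
    REWARD_ONSET_S,
    RESPONSE_WINDOW_S,
    SESSION_LEAD_S,
    STIM_DURATION_S,
    STIM_ONSET_S,
    TRIAL_WINDOW_S,
    SimConfig,
)
from .errors import ConfigError, EmptySessionError, GeometryError
from .fluorescence import RoiMaskSet, TraceMatrix
from .registration import FrameStack
from .pupil import PupilTrace

#: Center (s after stimulus onset) and width (s) of the task-evoked
#: pupil dilation; the peak lands in the post-tactile analysis window.
PUPIL_BUMP_CENTER_S = 1.2
PUPIL_BUMP_SIGMA_S = 0.8

_SNAP_HZ = 15.0  # trial starts live on this grid (divides 30 Hz and 15 Hz)


@dataclass
class GroundTruth:
    """Everything the generator injected, for validation.

    ``true_events`` maps each ROI id to its (onset s, amplitude dF/F)
    pairs (onsets are session-absolute and grid-aligned); branch ROIs
    of one axon carry identical lists.  ``event_table`` is the same
    information in tidy form with trial and epoch labels.
    """

    true_events: dict[str, list[tuple[float, float]]]
    duplicate_map: dict[str, str]              # ROI id -> parent axon id
    injected_probs: dict
    outcome_labels: pd.Series
    event_table: pd.DataFrame
    shift_series: np.ndarray | None = None     # (n_frames, 2) (dx, dy)
    pupil_artifact_trials: list[int] = field(default_factory=list)


def _snap(t: float) -> float:
    return round(t * _SNAP_HZ) / _SNAP_HZ


def simulate_trials(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample a trial table: types, timing anchors, outcomes, lick trains.

    The tactile stimulus (or its virtual time on catch trials) falls
    3 s after trial start; rewarded trials record reward delivery at
    the end of the 1.5 s response window.  Lick trains are constructed
    to be consistent with the sampled outcome under the task mode.
    """
    if config.n_trials == 0:
        raise EmptySessionError("cannot simulate a session with zero trials")
    rows = []
    t_start = _snap(SESSION_LEAD_S)
    for trial_id in range(config.n_trials):
        is_catch = rng.random() < config.catch_fraction
        t_stim = t_start + STIM_ONSET_S
        if is_catch:
            outcome = "FA" if rng.random() < config.fa_rate else "CR"
        else:
            outcome = "HIT" if rng.random() < config.hit_rate else "MISS"
        rewarded = outcome == "HIT"  # both task modes reward correct HITs
        t_reward = t_start + REWARD_ONSET_S if rewarded else np.nan

        licks: list[float] = []
        if config.task_mode == "action":
            if outcome == "HIT":
                latency = _lick_latency_s(config, rng)
                licks = _lick_bout(t_stim + latency, t_reward + 1.5, config, rng)
            elif outcome == "FA":
                first = t_stim + rng.uniform(0.05, RESPONSE_WINDOW_S - 0.05)
                licks = _lick_bout(first, first + 1.0, config, rng)
        else:  # suppression
            if outcome == "HIT":
                first = t_reward + _lick_latency_s(config, rng)
                licks = _lick_bout(first, t_reward + 2.0, config, rng)
            elif outcome == "MISS":  # early lick aborts the trial
                first = t_stim + rng.uniform(0.05, RESPONSE_WINDOW_S - 0.05)
                licks = _lick_bout(first, first + 0.8, config, rng)
            elif outcome == "FA":
                first = t_stim + rng.uniform(0.05, RESPONSE_WINDOW_S - 0.05)
                licks = _lick_bout(first, first + 1.0, config, rng)
        rows.append(
            {
                "trial_id": trial_id,
                "trial_type": "catch" if is_catch else "stimulus",
                "t_start": t_start,
                "t_stimulus": t_stim,
                "t_reward": t_reward,
                "lick_times": licks,
                "outcome": outcome,
                "task_mode": config.task_mode,
            }
        )
        iti = rng.uniform(*ITI_RANGE_S)
        t_start = _snap(t_start + TRIAL_WINDOW_S + iti)
    return pd.DataFrame(rows)


def _lick_latency_s(config: SimConfig, rng: np.random.Generator) -> float:
    mean, sd = config.lick_latency_ms, config.lick_latency_sd_ms
    if sd <= 0:
        return mean / 1000.0
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    latency = float(rng.lognormal(mu, np.sqrt(sigma2)))
    return float(np.clip(latency, 60.0, RESPONSE_WINDOW_S * 1000.0 - 50.0)) / 1000.0


def _lick_bout(first: float, until: float, config: SimConfig, rng: np.random.Generator) -> list[float]:
    licks = [first]
    t = first
    period = 1.0 / config.lick_bout_hz
    while True:
        t += period * rng.uniform(0.8, 1.2)
        if t >= until:
            break
        licks.append(t)
    return [round(float(x), 4) for x in licks]


def calcium_kernel(frame_rate: float, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Difference-of-exponentials transient kernel, unit peak on the grid.

    Sampled at t = (j + 1) / frame_rate starting at the onset frame, so
    an injected transient is already a substantial fraction of its peak
    at its onset sample.  Truncated where the tail falls below 1e-6 of
    the peak.
    """
    tau_r, tau_d = rise_ms / 1000.0, decay_ms / 1000.0
    dt = 1.0 / frame_rate
    n = int(np.ceil((tau_d * np.log(1e6) + 5 * tau_r) / dt)) + 1
    t = (np.arange(n) + 1) * dt
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    peak = k.max()
    if peak <= 0:
        raise ConfigError("degenerate kernel: rise must be faster than decay")
    return k / peak


def _epoch_windows_for_trial(trial) -> dict[str, tuple[float, float]]:
    """Session-absolute injection windows for one trial (reward if rewarded)."""
    t_stim = trial.t_stimulus
    windows = {
        "spontaneous": (t_stim - 2.0, t_stim - 1.0),
        "stimulus": (t_stim, t_stim + STIM_DURATION_S),
        "response": (t_stim, t_stim + 1.0),
    }
    if np.isfinite(trial.t_reward):
        windows["reward"] = (trial.t_reward, trial.t_reward + 1.0)
    return windows


def _lognormal_amplitude(config: SimConfig, rng: np.random.Generator) -> float:
    mean, sd = config.amplitude_mean, config.amplitude_sd
    if sd <= 0:
        return mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def roi_id_for(axon: int, branch: int) -> str:
    return f"axon{axon:03d}.{branch}"


def simulate_traces(
    trials: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> tuple[TraceMatrix, GroundTruth]:
    """Generate raw ROI fluorescence traces plus their ground truth.

    One transient at most is injected per axon, epoch, and trial; the
    injected onset is floored to the frame grid and recorded.  Branch
    ROIs replicate the parent axon's dF/F signal with independent noise
    and drift phase.
    """
    if trials.empty:
        raise EmptySessionError("simulate_traces needs a nonempty trial table")
    for name in config.epoch_event_prob:
        if name not in CANONICAL_EPOCH_NAMES:
            raise ConfigError(f"unknown epoch {name!r} in epoch_event_prob")
    rate = config.frame_rate
    dt = 1.0 / rate
    session_end = float(trials["t_start"].iloc[-1]) + TRIAL_WINDOW_S + 1.0
    n_frames = int(np.ceil(session_end * rate))
    frame_times = np.arange(n_frames) * dt

    kernel = calcium_kernel(rate, config.kernel_rise_ms, config.kernel_decay_ms)
    impulses = np.zeros((config.n_axons, n_frames))
    event_rows = []
    axon_events: dict[int, list[tuple[float, float]]] = {a: [] for a in range(config.n_axons)}
    for axon in range(config.n_axons):
        for trial in trials.itertuples():
            windows = _epoch_windows_for_trial(trial)
            for epoch in CANONICAL_EPOCH_NAMES:
                if epoch not in windows:
                    continue
                p = config.event_prob(epoch, trial.outcome)
                if p <= 0 or rng.random() >= p:
                    continue
                lo, hi = windows[epoch]
                onset = rng.uniform(lo, hi)
                frame = int(np.floor(onset * rate))
                onset_s = frame * dt
                amp = _lognormal_amplitude(config, rng)
                impulses[axon, frame] += amp
                axon_events[axon].append((onset_s, amp))
                event_rows.append(
                    {
                        "axon": axon,
                        "trial_id": int(trial.trial_id),
                        "epoch": epoch,
                        "onset_s": onset_s,
                        "amplitude": amp,
                    }
                )
    dff = fftconvolve(impulses, kernel[None, :], mode="full", axes=1)[:, :n_frames]

    n_rois = config.n_axons * config.branches_per_axon
    roi_ids, duplicate_map, true_events = [], {}, {}
    values = np.empty((n_rois, n_frames))
    phases = rng.uniform(0, 2 * np.pi, size=n_rois)
    i = 0
    for axon in range(config.n_axons):
        for branch in range(config.branches_per_axon):
            roi_id = roi_id_for(axon, branch)
            roi_ids.append(roi_id)
            duplicate_map[roi_id] = f"axon{axon:03d}"
            true_events[roi_id] = list(axon_events[axon])
            drift = config.drift_amplitude * np.sin(
                2 * np.pi * frame_times / config.drift_period_s + phases[i]
            )
            noise = rng.normal(0.0, config.noise_sd, n_frames) if config.noise_sd > 0 else 0.0
            values[i] = config.f0_level * (1.0 + dff[axon]) + drift + noise
            i += 1
    np.clip(values, 0.0, None, out=values)

    event_table = pd.DataFrame(
        event_rows, columns=["axon", "trial_id", "epoch", "onset_s", "amplitude"]
    )
    gt = GroundTruth(
        true_events=true_events,
        duplicate_map=duplicate_map,
        injected_probs={k: v for k, v in config.epoch_event_prob.items()},
        outcome_labels=trials.set_index("trial_id")["outcome"].copy(),
        event_table=event_table,
    )
    traces = TraceMatrix(values, frame_times, roi_ids, rate)
    return traces, gt


def make_masks(
    config: SimConfig,
    rng: np.random.Generator,
    radius_px: int = 3,
    margin_px: int = 16,
    min_separation_px: float = 12.0,
) -> RoiMaskSet:
    """Random non-overlapping disk masks, one per ROI, inside the FOV."""
    h, w = config.fov_shape
    n_rois = config.n_axons * config.branches_per_axon
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_rois:
        attempts += 1
        if attempts > 20000:
            raise GeometryError("could not place all ROIs; FOV too small")
        r = rng.uniform(margin_px, h - margin_px)
        c = rng.uniform(margin_px, w - margin_px)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_separation_px**2 for r0, c0 in centers):
            centers.append((r, c))
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    disk = yy**2 + xx**2 <= radius_px**2
    drows, dcols = np.nonzero(disk)
    pixels = {}
    i = 0
    for axon in range(config.n_axons):
        for branch in range(config.branches_per_axon):
            r0, c0 = centers[i]
            rows = drows - radius_px + int(round(r0))
            cols = dcols - radius_px + int(round(c0))
            pixels[roi_id_for(axon, branch)] = (rows, cols)
            i += 1
    return RoiMaskSet(pixels)


def simulate_frames(
    traces: TraceMatrix,
    masks: RoiMaskSet,
    config: SimConfig,
    rng: np.random.Generator,
    ground_truth: GroundTruth | None = None,
    background: float = 10.0,
    blob_sigma_px: float = 2.0,
) -> tuple[FrameStack, np.ndarray]:
    """Render traces as Gaussian blobs and apply rigid per-frame shifts.

    Each frame is the background plus, per ROI, a Gaussian blob at the
    mask centroid whose peak equals that frame's fluorescence value,
    plus white noise; a piecewise-constant integer shift (one draw per
    ``shift_block_s`` block, |shift| <= ``max_shift_px``) is then
    applied circularly.  The applied (dx, dy) series is returned and,
    when a :class:`GroundTruth` is passed, recorded on it.

    Intended for modest FOVs and stack lengths (validation material);
    a full 512 x 512 session does not fit comfortably in memory.
    """
    masks.check_within(config.fov_shape)
    h, w = config.fov_shape
    n_frames = traces.values.shape[1]

    blobs = np.zeros((len(masks), h, w))
    for i, (r0, c0) in enumerate(masks.centroids().values()):
        yy = np.arange(h)[:, None] - r0
        xx = np.arange(w)[None, :] - c0
        blobs[i] = np.exp(-(yy**2 + xx**2) / (2 * blob_sigma_px**2))

    block = max(1, int(round(config.shift_block_s * traces.frame_rate)))
    n_blocks = int(np.ceil(n_frames / block))
    block_shifts = rng.integers(-config.max_shift_px, config.max_shift_px + 1, size=(n_blocks, 2))
    shifts = np.repeat(block_shifts, block, axis=0)[:n_frames]  # (dx, dy)

    frames = np.empty((n_frames, h, w), dtype=np.float32)
    flat_blobs = blobs.reshape(len(masks), -1)
    for t in range(n_frames):
        img = background + traces.values[:, t] @ flat_blobs
        img = img.reshape(h, w)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=(h, w))
        dx, dy = int(shifts[t, 0]), int(shifts[t, 1])
        frames[t] = np.roll(img, (dy, dx), axis=(0, 1))
    if ground_truth is not None:
        ground_truth.shift_series = shifts
    stack = FrameStack(frames, traces.frame_rate, traces.frame_times.copy())
    return stack, shifts


def simulate_pupil(
    trials: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    ground_truth: GroundTruth | None = None,
) -> PupilTrace:
    """Pupil diameter trace: baseline + slow noise + task-evoked dilation.

    Every trial carries a smooth dilation bump peaking
    ~1.2 s after (virtual) stimulus onset — the animal is engaged for
    the session — with amplitude ``pupil_bump_mm``.  With probability
    ``pupil_artifact_rate`` per trial a brief eyelid-closure dropout is
    inserted and flagged.
    """
    if trials.empty:
        raise EmptySessionError("simulate_pupil needs a nonempty trial table")
    rate = config.pupil_rate
    dt = 1.0 / rate
    session_end = float(trials["t_start"].iloc[-1]) + TRIAL_WINDOW_S + 1.0
    n = int(np.ceil(session_end * rate))
    times = np.arange(n) * dt

    diameter = np.full(n, config.pupil_baseline_mm)
    if config.pupil_noise_sd_mm > 0:
        white = rng.normal(0.0, 1.0, n)
        slow = gaussian_filter1d(white, sigma=rate)  # ~1 s smoothing
        sd = slow.std()
        if sd > 0:
            diameter = diameter + slow * (config.pupil_noise_sd_mm / sd)

    if config.pupil_bump_mm != 0:
        for t_stim in trials["t_stimulus"]:
            center = t_stim + PUPIL_BUMP_CENTER_S
            lo = int(max(0, np.floor((center - 4 * PUPIL_BUMP_SIGMA_S) * rate)))
            hi = int(min(n, np.ceil((center + 4 * PUPIL_BUMP_SIGMA_S) * rate)))
            tt = times[lo:hi]
            diameter[lo:hi] += config.pupil_bump_mm * np.exp(
                -((tt - center) ** 2) / (2 * PUPIL_BUMP_SIGMA_S**2)
            )

    artifact = np.zeros(n, dtype=bool)
    artifact_trials: list[int] = []
    if config.pupil_artifact_rate > 0:
        for trial in trials.itertuples():
            if rng.random() >= config.pupil_artifact_rate:
                continue
            start = trial.t_start + rng.uniform(0.0, TRIAL_WINDOW_S - 0.4)
            lo = int(np.floor(start * rate))
            hi = min(n, lo + int(round(0.3 * rate)))
            artifact[lo:hi] = True
            diameter[lo:hi] = 0.05  # eyelid covering the pupil
            artifact_trials.append(int(trial.trial_id))
    if ground_truth is not None:
        ground_truth.pupil_artifact_trials = artifact_trials
    return PupilTrace(times, diameter, artifact)


@dataclass
class SyntheticSession:
    """A fully generated session: trials, traces, pupil, ground truth."""

    config: SimConfig
    trials: pd.DataFrame
    traces: TraceMatrix
    pupil: PupilTrace
    ground_truth: GroundTruth


def simulate_session(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SyntheticSession:
    """Generate trials, fluorescence traces and pupil for one session.

    Uses ``config.seed`` when no generator is supplied; identical
    configurations and seeds reproduce the session bit for bit.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    trials = simulate_trials(config, rng)
    traces, gt = simulate_traces(trials, config, rng)
    pupil = simulate_pupil(trials, config, rng, ground_truth=gt)
    return SyntheticSession(config, trials, traces, pupil, gt)
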