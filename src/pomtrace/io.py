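"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: trial tables, traces (long format),
events, shifts, pupil traces and epoch statistics as CSV; ground truth
and dedup reports as JSON; frame stacks and mask label images as
(multi-page) TIFF via tifffile; configs as YAML.

Epoch-statistics CSVs are written with a fixed float format and row
order so that identical analyses produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import TRIAL_COLUMNS
from .errors import PomtraceError
from .events import DedupResult
from .fluorescence import RoiMaskSet, TraceMatrix
from .pupil import PupilTrace
from .registration import FrameStack, ShiftSeries
from .synth import GroundTruth

_FLOAT_FMT = "%.10g"


# --- trial tables ----------------------------------------------------------
def write_trials(trials: pd.DataFrame, path) -> None:
    out = trials.copy()
    out["lick_times"] = [
        ";".join(f"{t:.4f}" for t in np.asarray(licks, dtype=float))
        for licks in out["lick_times"]
    ]
    out[TRIAL_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["lick_times"] = [
        [float(x) for x in str(s).split(";") if x not in ("", "nan")]
        for s in df["lick_times"].fillna("")
    ]
    return df


# --- traces ----------------------------------------------------------------
def write_traces(traces: TraceMatrix, path) -> None:
    """Long-format CSV: roi_id, frame_time, value."""
    n_rois, n_frames = traces.values.shape
    df = pd.DataFrame(
        {
            "roi_id": np.repeat(traces.roi_ids, n_frames),
            "frame_time": np.tile(traces.frame_times, n_rois),
            "value": traces.values.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_traces(path) -> TraceMatrix:
    df = pd.read_csv(path)
    roi_ids = list(pd.unique(df["roi_id"]))
    frame_times = np.sort(df["frame_time"].unique())
    wide = df.pivot(index="roi_id", columns="frame_time", values="value")
    wide = wide.loc[roi_ids, frame_times]
    if len(frame_times) < 2:
        raise PomtraceError("trace file has fewer than two time points")
    # global fit of the rate: robust to per-timestamp rounding in the CSV
    rate = (len(frame_times) - 1) / float(frame_times[-1] - frame_times[0])
    return TraceMatrix(wide.to_numpy(), frame_times, [str(r) for r in roi_ids], rate)


# --- events / shifts / stats ----------------------------------------------
def write_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_shifts(shifts: ShiftSeries, path) -> None:
    shifts.to_dataframe().to_csv(path, index=False, lineterminator="\n")


def write_epoch_stats(stats: pd.DataFrame, path) -> None:
    """Deterministic tidy CSV of per-ROI/epoch/outcome statistics."""
    out = stats.sort_values(["roi_id", "epoch", "outcome"]).reset_index(drop=True)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def write_dedup_report(result: DedupResult, path) -> None:
    payload = {
        "kept_roi_ids": result.kept_roi_ids,
        "removed_roi_ids": result.removed_roi_ids,
        "duplicate_groups": result.duplicate_groups,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# --- pupil -----------------------------------------------------------------
def write_pupil(trace: PupilTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.times,
            "diameter_mm": trace.diameter,
            "artifact": trace.artifact.astype(int),
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_pupil(path) -> PupilTrace:
    df = pd.read_csv(path)
    return PupilTrace(
        df["time_s"].to_numpy(),
        df["diameter_mm"].to_numpy(),
        df["artifact"].to_numpy().astype(bool),
    )


# --- ground truth ----------------------------------------------------------
def write_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "true_events": {k: [[float(o), float(a)] for o, a in v] for k, v in gt.true_events.items()},
        "duplicate_map": gt.duplicate_map,
        "injected_probs": gt.injected_probs,
        "outcome_labels": {int(k): v for k, v in gt.outcome_labels.items()},
        "event_table": gt.event_table.to_dict(orient="records"),
        "shift_series": None if gt.shift_series is None else np.asarray(gt.shift_series).tolist(),
        "pupil_artifact_trials": gt.pupil_artifact_trials,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        true_events={k: [(o, a) for o, a in v] for k, v in d["true_events"].items()},
        duplicate_map=d["duplicate_map"],
        injected_probs=d["injected_probs"],
        outcome_labels=pd.Series({int(k): v for k, v in d["outcome_labels"].items()}).rename_axis(
            "trial_id"
        ),
        event_table=pd.DataFrame(
            d["event_table"], columns=["axon", "trial_id", "epoch", "onset_s", "amplitude"]
        ),
        shift_series=None if d["shift_series"] is None else np.asarray(d["shift_series"]),
        pupil_artifact_trials=list(d.get("pupil_artifact_trials", [])),
    )


# --- TIFF ------------------------------------------------------------------
def write_stack(stack: FrameStack, path) -> None:
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")


def read_stack(path, frame_rate: float) -> FrameStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(np.asarray(frames, dtype=float), frame_rate)


def write_masks(masks: RoiMaskSet, shape: tuple[int, int], path) -> None:
    tifffile.imwrite(path, masks.to_label_image(shape))


def read_masks(path, roi_ids: list[str] | None = None) -> RoiMaskSet:
    return RoiMaskSet.from_label_image(tifffile.imread(path), roi_ids)
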