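"""Rigid motion correction by whole-frame cross-correlation.

Lateral drifts of the imaging field are corrected by registering each
frame to a reference image.  The per-frame rigid shift is the integer
pixel offset maximizing the 2-D cross-correlation between the
mean-subtracted frame and reference, computed as a frequency-domain
product; ties are broken toward the zero shift.  The reference image is
the average of frames whose drift relative to a provisional anchor (the
pixelwise temporal median of the stack) is minimal (< 15 px).

Shifts of 15 px or more are flagged rather than discarded; downstream
trace extraction marks samples from flagged frames as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PomtraceError, ReferenceError_

#: Drift magnitude (pixels, per axis) at and above which a frame is flagged.
DRIFT_FLAG_PX = 15


@dataclass
class FrameStack:
    """A time x height x width fluorescence movie with a frame clock."""

    frames: np.ndarray
    frame_rate: float
    frame_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise PomtraceError(f"frames must be 3-D, got shape {self.frames.shape}")
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames) / self.frame_rate
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frame_times) != self.n_frames:
            raise PomtraceError("frame_times length must equal frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise PomtraceError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ShiftSeries:
    """Per-frame integer rigid shifts (dx = columns, dy = rows)."""

    dx: np.ndarray
    dy: np.ndarray
    flagged: np.ndarray

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=int)
        self.dy = np.asarray(self.dy, dtype=int)
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if not (len(self.dx) == len(self.dy) == len(self.flagged)):
            raise PomtraceError("shift series components must have equal length")

    def __len__(self) -> int:
        return len(self.dx)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self)),
                "dx": self.dx,
                "dy": self.dy,
                "flagged": self.flagged,
            }
        )


def _wrap_signed(idx: np.ndarray, size: int) -> np.ndarray:
    """Map circular correlation lags to signed shifts in (-size/2, size/2]."""
    idx = np.asarray(idx)
    return np.where(idx > size // 2, idx - size, idx)


def best_shift(frame: np.ndarray, ref: np.ndarray) -> tuple[int, int, bool]:
    """Integer shift (dx, dy) maximizing cross-correlation of ``frame`` with ``ref``.

    Both images are mean-subtracted; the circular cross-correlation
    surface is computed via an FFT product and its argmax located.  If
    several lags tie (to within numerical precision), the
    smallest-magnitude shift wins, with a final lexicographic (dy, dx)
    tie-break for determinism.

    Returns ``(dx, dy, degenerate)`` such that
    ``frame ~ roll(ref, (dy, dx))``; ``degenerate`` is True when the
    frame (or reference) has zero variance, in which case the shift is
    (0, 0).
    """
    a = frame.astype(float) - float(np.mean(frame))
    b = ref.astype(float) - float(np.mean(ref))
    if not np.any(a) or not np.any(b):
        return 0, 0, True
    cc = np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))).real
    cmax = cc.max()
    tol = 1e-9 * max(1.0, abs(cmax))
    rows, cols = np.nonzero(cc >= cmax - tol)
    h, w = cc.shape
    dys = _wrap_signed(rows, h)
    dxs = _wrap_signed(cols, w)
    order = np.lexsort((dxs, dys, np.abs(dxs), np.abs(dys), dys**2 + dxs**2))
    best = order[0]
    return int(dxs[best]), int(dys[best]), False


def apply_shift(img: np.ndarray, dx: int, dy: int, fill: float) -> np.ndarray:
    """Translate ``img`` by (dx, dy) pixels, filling vacated pixels with ``fill``."""
    out = np.full_like(img, fill)
    h, w = img.shape
    if abs(dy) >= h or abs(dx) >= w:
        return out
    src_r = slice(max(0, -dy), min(h, h - dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_r = slice(max(0, dy), min(h, h + dy))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def build_reference(stack: FrameStack, drift_threshold_px: float = DRIFT_FLAG_PX) -> np.ndarray:
    """Average the low-drift frames of a stack into a reference image.

    A provisional anchor (pixelwise temporal median of the stack) is
    correlated against every frame; frames whose shift is below
    ``drift_threshold_px`` in both axes are averaged.  Raises
    :class:`ReferenceError_` if no frame qualifies.
    """
    if stack.n_frames < 2:
        raise PomtraceError("build_reference needs at least 2 frames")
    anchor = np.median(stack.frames, axis=0)
    keep = []
    for frame in stack.frames:
        dx, dy, _ = best_shift(frame, anchor)
        if abs(dx) < drift_threshold_px and abs(dy) < drift_threshold_px:
            keep.append(frame)
    if not keep:
        raise ReferenceError_(
            f"no frame drifts below {drift_threshold_px} px; cannot build a reference"
        )
    return np.mean(np.asarray(keep, dtype=float), axis=0)


def register_frames(
    stack: FrameStack,
    ref: np.ndarray,
    flag_threshold_px: float = DRIFT_FLAG_PX,
) -> tuple[FrameStack, ShiftSeries]:
    """Register every frame of ``stack`` to ``ref`` by integer rigid shifts.

    Each frame's measured shift is inverted and applied; pixels moved
    into view are filled with the frame's median intensity.  Frames with
    a shift magnitude >= ``flag_threshold_px`` in either axis, or with
    zero variance, are flagged.
    """
    if ref.shape != stack.shape:
        raise PomtraceError(f"reference shape {ref.shape} != frame shape {stack.shape}")
    n = stack.n_frames
    dxs = np.zeros(n, dtype=int)
    dys = np.zeros(n, dtype=int)
    flagged = np.zeros(n, dtype=bool)
    corrected = np.empty_like(stack.frames, dtype=float)
    for i, frame in enumerate(stack.frames):
        dx, dy, degenerate = best_shift(frame, ref)
        dxs[i], dys[i] = dx, dy
        flagged[i] = degenerate or max(abs(dx), abs(dy)) >= flag_threshold_px
        corrected[i] = apply_shift(frame, -dx, -dy, fill=float(np.median(frame)))
    out = FrameStack(corrected, stack.frame_rate, stack.frame_times.copy())
    return out, ShiftSeries(dxs, dys, flagged)
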