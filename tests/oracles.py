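"""Independent brute-force oracles used to validate pipeline stages.

These deliberately avoid the package's own vectorized implementations:
the event oracle walks each trace sample by sample, and the shift
oracle evaluates the correlation of every candidate shift explicitly.
"""

from __future__ import annotations

import numpy as np


def brute_force_events(
    x: np.ndarray, threshold: float, dt: float, min_duration_ms: float = 200.0
) -> list[tuple[int, int, float]]:
    """Enumerate every contiguous suprathreshold run by linear scan.

    Returns (onset_index, offset_index, peak) triples for runs strictly
    longer than ``min_duration_ms``; ``offset_index`` is the first index
    back below threshold (``len(x)`` when the run touches the end).
    NaN samples are below threshold by definition, splitting runs.
    """
    events = []
    n = len(x)
    i = 0
    while i < n:
        above = np.isfinite(x[i]) and x[i] > threshold
        if not above:
            i += 1
            continue
        j = i
        while j < n and np.isfinite(x[j]) and x[j] > threshold:
            j += 1
        # duration measured as sample count over the rate (dt = 1/rate)
        if (j - i) * dt * 1000.0 > min_duration_ms:
            events.append((i, j, float(np.max(x[i:j]))))
        i = j
    return events


def exhaustive_best_shift(
    frame: np.ndarray, ref: np.ndarray, max_shift: int
) -> tuple[int, int]:
    """Best (dx, dy) by explicitly correlating every circular shift of ref."""
    a = frame - frame.mean()
    b = ref - ref.mean()
    best, best_val = (0, 0), -np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            val = float(np.sum(a * np.roll(b, (dy, dx), axis=(0, 1))))
            better = val > best_val + 1e-9
            tie = abs(val - best_val) <= 1e-9 and (dy * dy + dx * dx) < (
                best[1] ** 2 + best[0] ** 2
            )
            if better or tie:
                best, best_val = (dx, dy), max(val, best_val)
    return best


def binom_ci99(p: float, n: int) -> tuple[float, float]:
    """Central 99% interval of a Binomial(n, p) proportion."""
    from scipy import stats

    lo = stats.binom.ppf(0.005, n, p) / n
    hi = stats.binom.ppf(0.995, n, p) / n
    return float(lo), float(hi)
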