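"""Behavioral outcome classification and performance metrics.

Trials of the tactile go/no-go task are classified from lick times into
the four signal-detection outcomes.  In the *action* task a lick within
the 1.5 s response window after stimulus onset on a stimulus trial is a
HIT (no lick: MISS); on a catch trial a lick in the same window is a
false alarm (FA), withholding is a correct rejection (CR).  In the
*suppression* task the contingency on stimulus trials is inverted:
withholding licking for the full window is a HIT, an early lick a MISS.

Session performance is summarized as d' = z(H) - z(F) (z: standard
normal quantile; extreme rates adjusted by the 1/(2N) rule) and as the
correct fraction (HIT + CR) / (stimulus + catch trials); sessions at or
above 80% correct count as expert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RESPONSE_WINDOW_S
from .errors import ConfigError, PomtraceError

#: Learning criterion: fraction of correct trials for an expert session.
EXPERT_CORRECT_FRACTION = 0.8

TRIAL_COLUMNS = [
    "trial_id",
    "trial_type",
    "t_start",
    "t_stimulus",
    "t_reward",
    "lick_times",
    "outcome",
    "task_mode",
]


def _licks_in_window(licks, lo: float, hi: float) -> bool:
    licks = np.asarray(licks, dtype=float)
    return bool(np.any((licks >= lo) & (licks < hi)))


def classify_outcomes(
    trials: pd.DataFrame, response_window_s: float = RESPONSE_WINDOW_S
) -> pd.DataFrame:
    """Fill the ``outcome`` column from lick times and task mode.

    The response window is half-open: a lick at exactly
    ``t_stimulus + response_window_s`` falls outside it.  Catch trials
    use the virtual stimulus time recorded in ``t_stimulus``.
    """
    out = trials.copy()
    outcomes = []
    for trial in out.itertuples():
        if trial.task_mode not in ("action", "suppression"):
            raise ConfigError(f"unknown task_mode {trial.task_mode!r}")
        licked = _licks_in_window(
            trial.lick_times, trial.t_stimulus, trial.t_stimulus + response_window_s
        )
        if trial.trial_type == "catch":
            outcomes.append("FA" if licked else "CR")
        elif trial.task_mode == "action":
            outcomes.append("HIT" if licked else "MISS")
        else:  # suppression: withholding is correct, an early lick a MISS
            outcomes.append("MISS" if licked else "HIT")
    out["outcome"] = outcomes
    return out


@dataclass
class DPrimeResult:
    d_prime: float
    z_hit: float
    z_fa: float


def dprime(
    hit_rate: float,
    fa_rate: float,
    n_signal: int | None = None,
    n_noise: int | None = None,
) -> DPrimeResult:
    """Sensitivity d' = z(H) - z(F) with the 1/(2N) extreme-rate rule.

    Rates of exactly 0 or 1 are replaced by 1/(2N) and 1 - 1/(2N)
    before the normal-quantile transform (N = the relevant trial
    count); an extreme rate with no usable N is an error.
    """
    def adjust(rate: float, n: int | None, label: str) -> float:
        if not 0.0 <= rate <= 1.0:
            raise PomtraceError(f"{label} must be in [0, 1], got {rate}")
        if rate in (0.0, 1.0):
            if not n:
                raise PomtraceError(
                    f"{label} of exactly {rate} needs a trial count for the 1/(2N) rule"
                )
            rate = 1.0 / (2 * n) if rate == 0.0 else 1.0 - 1.0 / (2 * n)
        return rate

    z_hit = float(stats.norm.ppf(adjust(hit_rate, n_signal, "hit rate")))
    z_fa = float(stats.norm.ppf(adjust(fa_rate, n_noise, "false-alarm rate")))
    return DPrimeResult(z_hit - z_fa, z_hit, z_fa)


def correct_fraction(n_hit: int, n_cr: int, n_stimulus: int, n_catch: int) -> float:
    """(HIT + CR) / (stimulus + catch trials)."""
    if min(n_hit, n_cr, n_stimulus, n_catch) < 0:
        raise PomtraceError("trial counts must be non-negative")
    denom = n_stimulus + n_catch
    if denom == 0:
        raise PomtraceError("correct_fraction undefined for zero trials")
    return (n_hit + n_cr) / denom


@dataclass
class BehaviorMetrics:
    """Session-level signal-detection summary."""

    hit_rate: float
    fa_rate: float
    d_prime: float
    z_hit: float
    z_fa: float
    correct_fraction: float
    is_expert: bool
    n_stimulus: int
    n_catch: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def session_metrics(
    trials: pd.DataFrame, expert_threshold: float = EXPERT_CORRECT_FRACTION
) -> BehaviorMetrics:
    """Compute H, F, d', and the correct fraction from classified trials."""
    counts = trials["outcome"].value_counts()
    n_hit, n_miss = int(counts.get("HIT", 0)), int(counts.get("MISS", 0))
    n_fa, n_cr = int(counts.get("FA", 0)), int(counts.get("CR", 0))
    n_stim, n_catch = n_hit + n_miss, n_fa + n_cr
    if n_stim == 0 or n_catch == 0:
        raise PomtraceError("session needs both stimulus and catch trials for d'")
    hit_rate, fa_rate = n_hit / n_stim, n_fa / n_catch
    res = dprime(hit_rate, fa_rate, n_signal=n_stim, n_noise=n_catch)
    frac = correct_fraction(n_hit, n_cr, n_stim, n_catch)
    return BehaviorMetrics(
        hit_rate,
        fa_rate,
        res.d_prime,
        res.z_hit,
        res.z_fa,
        frac,
        frac >= expert_threshold,
        n_stim,
        n_catch,
    )


def first_lick_latency(trials: pd.DataFrame) -> pd.Series:
    """Latency (ms) of the first lick after stimulus onset, per trial.

    Trials without a post-stimulus lick get a missing value.
    """
    latencies = {}
    for trial in trials.itertuples():
        licks = np.asarray(trial.lick_times, dtype=float)
        post = licks[licks >= trial.t_stimulus]
        latencies[int(trial.trial_id)] = (
            float((post[0] - trial.t_stimulus) * 1000.0) if post.size else np.nan
        )
    return pd.Series(latencies, name="first_lick_latency_ms").rename_axis("trial_id")


def lick_frequency(trials: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Lick rate (Hz) per trial per epoch window.

    ``windows`` holds trial-relative half-open windows as produced by
    :func:`pomtrace.epochs.assign_epoch_windows`.
    """
    starts = trials.set_index("trial_id")["t_start"]
    licks_by_id = trials.set_index("trial_id")["lick_times"]
    rows = []
    for win in windows.itertuples():
        licks = np.asarray(licks_by_id.loc[win.trial_id], dtype=float) - starts.loc[win.trial_id]
        count = int(np.sum((licks >= win.win_start) & (licks < win.win_end)))
        length = win.win_end - win.win_start
        rows.append(
            {
                "trial_id": win.trial_id,
                "epoch": win.epoch,
                "lick_hz": count / length,
            }
        )
    return pd.DataFrame(rows)


def lick_activity_correlation(
    lick_hz: pd.Series, activity: pd.Series, min_trials: int = 10
) -> tuple[float, float]:
    """Spearman rank correlation between per-trial lick rate and axon activity.

    ``activity`` is typically the per-trial mean event indicator across
    ROIs.  Returns ``(rho, p)``; both NaN when either series has zero
    variance (correlation undefined).
    """
    paired = pd.concat([lick_hz.rename("lick"), activity.rename("act")], axis=1).dropna()
    if len(paired) < min_trials:
        raise PomtraceError(f"need at least {min_trials} paired trials, got {len(paired)}")
    if paired["lick"].nunique() < 2 or paired["act"].nunique() < 2:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(paired["lick"], paired["act"])
    return float(rho), float(p)
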