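"""Session configuration and task timing.

The tactile go/no-go task has a fixed temporal skeleton: each trial opens
with a 3 s baseline, a 500 ms tactile stimulus (200 Hz vibration) is then
delivered, the animal has a 1.5 s response window, reward (when earned)
is delivered at the end of that window, followed by a 2 s retrieval
window.  Trials are separated by a randomized 4-7 s inter-trial interval.
The analysis window recorded for every trial runs from trial start to
2 s past the end of the reward-retrieval window (8.5 s), so that the
-2 s spontaneous window and post-reward frames always exist.

:class:`SimConfig` collects every tunable of the synthetic-session
generator.  Its defaults are the study conditions: ~300-trial sessions,
40% catch trials, 30 Hz imaging of a 512x512 px field of view with ~19
axonal ROIs, GCaMP6f-like transient kinetics, and per-epoch event
probabilities taken from the reported expert-session statistics
(spontaneous 0.08, response 0.32 on HIT trials, reward 0.12).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Union

import yaml

from .errors import ConfigError

# --- task temporal skeleton (seconds, trial-relative) ---------------------
BASELINE_S = 3.0           # silent baseline before the tactile stimulus
STIM_DURATION_S = 0.5      # 200 Hz vibration burst
RESPONSE_WINDOW_S = 1.5    # report (action) / withhold (suppression) window
REWARD_RETRIEVAL_S = 2.0   # window to collect the reward
POST_PAD_S = 2.0           # extra recorded tail after the retrieval window
TRIAL_WINDOW_S = BASELINE_S + RESPONSE_WINDOW_S + REWARD_RETRIEVAL_S + POST_PAD_S  # 8.5 s
ITI_RANGE_S = (4.0, 7.0)   # randomized inter-trial interval
SESSION_LEAD_S = 5.0       # recording lead-in before the first trial start

#: Stimulus onset relative to trial start.
STIM_ONSET_S = BASELINE_S
#: Reward delivery (when earned) relative to trial start: end of the
#: response window, cued by an auditory tone.
REWARD_ONSET_S = BASELINE_S + RESPONSE_WINDOW_S

CANONICAL_EPOCH_NAMES = ("spontaneous", "stimulus", "response", "reward")
TASK_MODES = ("action", "suppression")
OUTCOMES = ("HIT", "MISS", "FA", "CR")

# Probability of injecting a Ca2+ transient, per trial, per epoch.  A plain
# float applies to every outcome class; a mapping gives per-outcome rates.
EpochProb = Union[float, Mapping[str, float]]


def default_epoch_probs() -> dict[str, EpochProb]:
    """Per-epoch, per-trial transient probabilities of an expert session.

    Spontaneous and reward rates are outcome-independent here; the
    response rate depends on the behavioral outcome (correct HIT trials
    evoke transients far more reliably than MISS or catch trials).
    """
    return {
        "spontaneous": 0.08,
        "stimulus": 0.0,  # merged into "response" by default, as in analysis
        "response": {"HIT": 0.32, "MISS": 0.12, "FA": 0.15, "CR": 0.08},
        "reward": {"HIT": 0.12},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic-session generator.

    Fluorescence is generated in arbitrary detector units around
    ``f0_level``; transient amplitudes are in dF/F units and converted to
    raw fluorescence by multiplying by the baseline level.
    """

    n_trials: int = 300
    catch_fraction: float = 0.4
    frame_rate: float = 30.0                      # Hz
    fov_shape: tuple[int, int] = (512, 512)       # pixels (rows, cols)
    n_axons: int = 19
    branches_per_axon: int = 1
    epoch_event_prob: dict[str, EpochProb] = field(default_factory=default_epoch_probs)
    amplitude_mean: float = 1.0                   # dF/F, lognormal mean
    amplitude_sd: float = 0.3                     # dF/F, lognormal sd
    kernel_rise_ms: float = 50.0                  # GCaMP6f-like rise
    kernel_decay_ms: float = 400.0                # GCaMP6f-like decay
    noise_sd: float = 5.0                         # fluorescence units
    f0_level: float = 100.0                       # fluorescence units
    drift_amplitude: float = 3.0                  # slow sinusoidal drift
    drift_period_s: float = 300.0
    max_shift_px: int = 10                        # rigid motion in frames
    shift_block_s: float = 10.0                   # piecewise-constant drift
    task_mode: str = "action"
    # behavioral outcome sampling (outcomes are inputs to the analysis)
    hit_rate: float = 0.875
    fa_rate: float = 0.08
    lick_latency_ms: float = 350.0
    lick_latency_sd_ms: float = 80.0
    lick_bout_hz: float = 7.0
    # pupillometry
    pupil_rate: float = 15.0                      # Hz
    pupil_baseline_mm: float = 0.32
    pupil_bump_mm: float = 0.12                   # task-evoked dilation
    pupil_noise_sd_mm: float = 0.01
    pupil_artifact_rate: float = 0.0              # eyelid closures per trial
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.catch_fraction <= 1.0:
            raise ConfigError(f"catch_fraction must be in [0, 1], got {self.catch_fraction}")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be > 0")
        if self.kernel_rise_ms <= 0 or self.kernel_decay_ms <= 0:
            raise ConfigError("kernel time constants must be > 0")
        if self.n_axons < 1:
            raise ConfigError("n_axons must be >= 1")
        if self.branches_per_axon < 1:
            raise ConfigError("branches_per_axon must be >= 1")
        if self.task_mode not in TASK_MODES:
            raise ConfigError(f"task_mode must be one of {TASK_MODES}, got {self.task_mode!r}")
        for name in self.epoch_event_prob:
            if name not in CANONICAL_EPOCH_NAMES:
                raise ConfigError(
                    f"unknown epoch {name!r}; canonical epochs are {CANONICAL_EPOCH_NAMES}"
                )
        for name, prob in self.epoch_event_prob.items():
            values = prob.values() if isinstance(prob, Mapping) else (prob,)
            for p in values:
                if not 0.0 <= float(p) <= 1.0:
                    raise ConfigError(f"epoch_event_prob[{name!r}] out of [0, 1]: {p}")
        for rate_name in ("hit_rate", "fa_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{rate_name} must be in [0, 1], got {rate}")

    def event_prob(self, epoch: str, outcome: str) -> float:
        """Resolve the injection probability for one epoch/outcome pair."""
        prob = self.epoch_event_prob.get(epoch, 0.0)
        if isinstance(prob, Mapping):
            return float(prob.get(outcome, 0.0))
        return float(prob)

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fov_shape"] = list(self.fov_shape)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "fov_shape" in d:
            d["fov_shape"] = tuple(d["fov_shape"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
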