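# pomtrace

Analysis pipeline for **two-photon Ca²⁺ imaging of thalamocortical axons
during goal-directed behavior**. It is written for experiments in which
GCaMP-expressing axons of a higher-order thalamic nucleus (e.g. POm
projections to layer 1 of forepaw S1) are imaged at 30 Hz while a
head-fixed mouse performs a tactile go/no-go task, and it covers the full
path from raw frame stacks to the per-epoch statistics such studies
report — together with a synthetic-session generator that provides exact
ground truth for every stage.

## What it computes

- **Rigid motion correction.** Each frame is registered to a reference
  image (the average of low-drift frames, < 15 px) by the integer shift
  maximizing whole-frame cross-correlation; ties break toward zero and
  drifts ≥ 15 px are flagged.
- **ΔF/F.** Per ROI and trial, the baseline F₀ is the centered rolling
  median of per-trial pre-stimulus means (60 frames / 2 s before stimulus
  onset), and ΔF/F = (F − F₀)/F₀.
- **Transient detection.** An event is a run of ΔF/F samples above
  F₀ + 2·SD (SD pooled over pre-stimulus samples) lasting strictly longer
  than 200 ms; onset, offset, peak amplitude and duration are measured
  per event.
- **Axon deduplication.** ROI pairs whose events coincide (onsets within
  ±2 frames, or both silent) in > 95 % of trials are presumed branches of
  one axon; one survivor per connected group is kept.
- **Epoch statistics.** Per ROI, epoch and outcome class (HIT/MISS/FA/CR):
  transient probability per trial Σ event-trials / Σ trials in the
  spontaneous [−2, −1) s, response [0, +1) s (relative to stimulus onset)
  and reward [0, +1) s (relative to reward delivery) windows, plus evoked
  amplitude/duration, peak-epoch categorization, mass averages and
  normalized peak-sorted display matrices.
- **Behavior.** Outcome classification for action and suppression task
  modes, d′ = z(H) − z(F) with the 1/(2N) extreme-rate rule, correct
  fraction (HIT + CR)/(stimulus + catch) with the 80 % expert criterion,
  first-lick latency, lick frequency and lick–activity rank correlation.
- **Pupillometry.** 11-s trial alignment of pupil diameter traces and
  peak readout in baseline / pre-tactile / post-tactile windows with
  artifact handling.

## Worked example

Every capability has a narrative script under `examples/`. Running
`python examples/04_epoch_statistics.py` simulates an expert session
(19 axons × 60 trials) with injected per-epoch transient probabilities
and recovers them through the full pipeline:

```
HIT-trial transient probability per epoch (injected 0.32/0.12/0.08):
  response     0.298   amplitude 1.02 dF/F
  reward       0.114   amplitude 1.02 dF/F
  spontaneous  0.077   amplitude 1.10 dF/F

axons by peak-activity epoch:
peak_epoch
response       15
none            3
spontaneous     1

display matrix: 19 axons x 255 samples, row maxima all 1.0, sorted by peak time
mass average peaks at 3.93 s after trial start (stimulus at 3.0 s): 0.152 +- 0.015 dF/F
```

The estimated probabilities (0.298 / 0.114 / 0.077) recover the injected
generator rates within sampling error at this session size; most axons
are categorized as response-epoch axons, and the population mass average
peaks shortly after the stimulus — the signature of response-epoch
signaling. `examples/05_behavior_metrics.py` prints the behavioral side
(d′ ≈ 2.9, 92 % correct, ~350 ms first-lick latency, and a null
lick–activity correlation within HIT trials), and
`examples/06_pupillometry.py` the pupil peaks (≈ 0.32 mm baseline
rising to ≈ 0.44 mm post-tactile).

A thin CLI mirrors the file-based workflow:

```bash
pomtrace simulate --out session/ --seed 1
pomtrace report --traces session/traces.csv --trials session/trials.csv --out-dir report/
pomtrace register --stack raw.tif --out corrected.tif --shifts shifts.csv
```

## Layout

- `src/pomtrace/` — the library: `synth` (generator), `registration`,
  `fluorescence`, `events`, `epochs`, `behavior`, `pupil`, `pipeline`,
  `io`, `cli`.
- `examples/` — one short script per capability.
- `tests/` — unit, property and end-to-end suites, including
  brute-force oracles independent of the implementation.
- `docs/methods.md` — the model, parameter and design notes.
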