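# Methods

This note documents the models, parameters and design choices behind
pomtrace: what the analysis computes, what the synthetic-session
generator emulates, and where the design was genuinely open.

## The task and its temporal skeleton

Each trial of the tactile go/no-go task opens with a 3 s baseline; a
200 Hz, 500 ms tactile stimulus is then delivered (or withheld on catch
trials, which keep a *virtual* stimulus time at trial start + 3 s).
The animal has a 1.5 s response window; in the **action** mode a lick
inside the window on a stimulus trial is a HIT (rewarded at the end of
the window), no lick a MISS, and a lick on a catch trial a false alarm
(FA) versus a correct rejection (CR). In the **suppression** mode the
stimulus-trial contingency inverts: withholding for the full window is
the rewarded HIT and an early lick a MISS. Trials are separated by a
randomized 4–7 s inter-trial interval. The recorded analysis window per
trial runs from trial start to 8.5 s (2 s past the end of the 2 s
reward-retrieval window), so the −2 s spontaneous window and
post-reward frames always exist. The response window is half-open,
[0, 1.5) s after stimulus onset: a lick at exactly +1.5 s falls outside.

Three 1-s analysis epochs anchor the statistics: **spontaneous**
[−2, −1) s and **response** [0, +1) s relative to stimulus onset, and
**reward** [0, +1) s relative to reward delivery (which the pipeline
places at stimulus + 1.5 s, the end of the response window; the reward
window therefore sits ~[1.5, 2.5) s post-stimulus). An optional split
of the response window into stimulus [0, 0.5) and response [0.5, 1.0)
sub-epochs is available but merged by default, since few axons respond
in the stimulus half-window alone. Reward windows exist only on
rewarded trials and are omitted — never zero-filled — elsewhere.

## Fluorescence model and ΔF/F

Baseline F₀ is estimated per ROI and trial in two steps: the mean raw
fluorescence over the 60 frames (2 s at 30 Hz) preceding stimulus onset
is taken per trial, and F₀(trial) is the centered rolling median of
these means over 5 trials, truncated at session edges. The 5-trial
window is a compromise: robust to a single outlier trial (a spontaneous
transient leaking into the baseline window) while still tracking slow
bleaching and drift. A trial with fewer than 80 % of its baseline
samples valid contributes no mean and is skipped by the median; an ROI
whose F₀ is non-positive on any trial is excluded with a logged reason.
ΔF/F = (F − F₀)/F₀ is scale-free: multiplying a raw trace by any
positive constant leaves it unchanged (property-tested).

The detection noise floor, `baseline_sd`, is the standard deviation of
the **pooled** pre-stimulus raw samples of the ROI across all trials
(a per-trial SD over 60 samples would be too unstable to threshold on).
Pooling does mean spontaneous transients that fall in the 2-s
pre-stimulus window inflate the estimate slightly, making the detector
marginally conservative; at the default signal-to-noise this costs
about 1 % of injected events.

## Transient detection

A transient is a maximal run of ΔF/F samples strictly above the
threshold 2·SD/F₀(trial) — the raw-fluorescence criterion F₀ + 2·SD
expressed in ΔF/F units — lasting strictly longer than 200 ms. At
30 Hz this means ≥ 7 consecutive suprathreshold samples: a 6-sample run
lasts exactly 200 ms and is rejected. The duration is computed from the
sample count divided by the frame rate so the boundary case is decided
exactly rather than by floating-point accident. Onset is the first
suprathreshold sample, offset the first sample back below threshold (a
run still above threshold at the trial-window end is closed one sample
past the last), the peak is the maximum in [onset, offset), and missing
samples (flagged registration frames) split runs at the gap. The
detector is validated sample-for-sample against an independent
brute-force scan on 1000 random mixed-SNR traces.

## Duplicate-branch removal

ROIs drawn over branches or boutons of one axon report the same
underlying spike train. Two phrasings of the exclusion rule circulate —
trace correlation versus per-trial event coincidence — and this package
implements the per-trial reading: for each ROI pair and trial,
agreement is 1 when both ROIs have events with onsets within ±2 frames
(~67 ms, a tolerance chosen to cover threshold-crossing jitter between
branches of different SNR) or both are silent; pairs agreeing in
> 95 % of trials are linked, connected components form duplicate
groups, and the member with the highest mean event amplitude (the
best-SNR branch) survives. Two silent ROIs technically agree on every
trial and would be grouped, but silent ROIs are excluded from all
statistics by the active-axon rule anyway. Single-trial sessions skip
deduplication with a warning, since a trial fraction over one trial is
meaningless.

## Epoch statistics

The headline quantity is the per-trial transient probability:
Σ event-trials / Σ trials, per ROI, epoch and outcome class, where a
trial counts once regardless of how many onsets fall in the window —
the statistic is a probability and is invariant to duplicating trials
(property-tested). Only **active axons** (≥ 1 detected transient in the
session) enter probability analyses; amplitude and duration statistics
additionally require ≥ 1 event in the analyzed epoch and use the first
event of each trial-epoch. Zero eligible trials yield a missing
statistic, never 0. Axons are categorized by the epoch containing the
global peak of their HIT-trial-averaged trace (first peak wins ties,
resolving toward the earlier epoch; flat traces and peaks outside all
windows are labeled "none"). The mass average averages over trials
within ROI and then over ROIs regardless of responsiveness, with SEM
across ROIs; display matrices normalize each ROI's averaged trace to
its maximum and sort rows by peak time with a stable id tie-break.

## Registration

Per-frame rigid shifts are estimated as the integer lag maximizing the
circular cross-correlation between the mean-subtracted frame and
reference, computed as a frequency-domain product. Integer shifts only:
the analysis consumes ROI means over many pixels, for which sub-pixel
registration gains little. Ties (within 1e−9 relative) break toward the
smaller-magnitude shift, then lexicographically, making the argmax
deterministic. The measured shift is inverted and applied with the
frame's median intensity filling vacated pixels; shifts ≥ 15 px in
either axis (and zero-variance frames) are flagged, and downstream
extraction marks samples of flagged frames as missing rather than
discarding frames outright. The reference image averages frames whose
drift relative to a provisional anchor — the pixelwise temporal median
of the stack, which needs no prior registration — is below threshold.
Note that averaging frames spread over several drift positions blurs
the reference and defines its own coordinate frame: measured shifts can
differ from externally known ones by a constant offset, and a tighter
reference threshold (e.g. 5 px) keeps the reference sharp when drifts
are large. Recovery is exact (all 841 integer shifts up to ±14 px at
SNR ≥ 5) against a sharp reference, and registration of an already
corrected stack is the identity.

## Behavior and pupillometry

d′ = z(H) − z(F) with z the standard-normal quantile; rates of exactly
0 or 1 are replaced by 1/(2N) and 1 − 1/(2N) (N the relevant trial
count), the standard signal-detection correction. The correct fraction
is (HIT + CR)/(stimulus + catch), with ≥ 80 % marking an expert
session. First-lick latency is the first lick after stimulus onset in
ms (missing when the animal never licks); lick frequency is counts over
window length; the lick–activity association uses Spearman rank
correlation between per-trial lick rate and the per-trial fraction of
active ROIs, reported missing when either series is constant. Switch
sessions (recorded at chance performance on a new contingency) are
classified with suppression-mode rules.

Pupil traces are split into 11-s trial windows (−4 to +7 s around trial
start), averaged per outcome class, and peaks read in the baseline
(−4..0 s from trial start), pre-tactile (−3..0 s from stimulus) and
post-tactile (0..+4 s from stimulus) windows. Artifact-flagged samples
(eyelid closures) are excluded, and a trial is dropped when more than
20 % of any window is flagged — a concrete rule standing in for manual
post-hoc artifact screening.

## The synthetic-session generator

The generator's defaults are the study conditions: ~300-trial sessions
with the catch fraction at its asymptotic 40 %, 30 Hz imaging of a
512 × 512 px field of view, 19 axonal ROIs per field, and per-epoch
transient probabilities of an expert session (spontaneous 0.08;
response 0.32 on HIT and lower on MISS/FA/CR; reward 0.12 on rewarded
trials). Outcomes are sampled from configurable HIT/FA rates (defaults
0.875 and 0.08, i.e. ~12.5 % MISS and d′ ≈ 2.5) — outcomes are inputs
to, not outputs of, the analysis, so no behavioral model is fit. Lick
trains are built to be consistent with the sampled outcome (first-lick
latency lognormal around 350 ms, ~7 Hz bouts).

Per axon, trial and epoch, at most one transient is injected (matching
the per-trial probability statistic), with onset uniform in the epoch
window and a lognormal ΔF/F amplitude (mean 1.0, SD 0.3). The impulse
train is convolved with a difference-of-exponentials kernel — rise
50 ms, decay 400 ms, GCaMP6f-like values chosen once as realistic
detector-test material, not fitted to data. The kernel is sampled at
t = (j+1)·Δt starting at the onset frame and normalized to unit peak on
that grid, so an injected transient is already suprathreshold at its
onset frame (avoiding a spurious one-frame onset latency that would
otherwise be a pure grid artifact) and its sampled peak equals the
drawn amplitude exactly. Ground-truth onsets are recorded grid-aligned.
Raw fluorescence is F₀·(1 + ΔF/F) plus a slow sinusoidal drift
(amplitude 3 % of baseline, 300 s period, random phase per ROI) and
white noise (SD 5 % of baseline); branch ROIs share the parent's event
train exactly and differ only in noise and drift phase. Trial starts
are snapped to the 1/15 s grid — the common multiple of the 30 Hz
imaging and 15 Hz pupil clocks — so trial-aligned sample grids are
identical across trials.

Frame rendering places a Gaussian blob at each ROI centroid scaled by
the trace value and applies a piecewise-constant integer shift
(redrawn every 10 s, |shift| ≤ `max_shift_px`) with circular roll;
since FFT cross-correlation is itself circular, shift recovery on
rendered stacks is exact. Rendering is intended for small fields of
view — a full 512 × 512 session does not fit comfortably in memory and
validation does not need it. The pupil model is a 0.32 mm baseline with
~1 s-smoothed noise and a Gaussian dilation bump (0.12 mm, σ = 0.8 s)
peaking 1.2 s after each trial's (virtual) stimulus — the animal is
treated as engaged throughout the session — plus optional 0.3 s
eyelid-closure dropouts.

**What the generator does not emulate**, and hence what passing tests
do not show about real recordings: no biophysical spike-to-indicator
model (transients are stereotyped kernels, so detector performance on
bursty or saturating real transients is untested); noise is white and
Gaussian rather than shot-noise-like and photon-limited; drift is
smooth and rigid (no z-drift, no non-rigid deformation); neuropil
contamination and bleaching beyond the rolling median are absent; and
outcomes are sampled, not generated by a learning animal, so
learning-curve dynamics are out of scope.

## Validation scale and numerical choices

The end-to-end recovery checks run at the study's cohort sizes — 418
ROIs × 40 trials for epoch probabilities, 159 ROIs for the HIT/MISS
contrast, 20 seeded replicates each — which completes in well under a
minute per cohort; the across-replicate mean of each epoch estimate is
required to land inside the 99 % binomial interval of the injected
value at one session's draw count, and the
response > reward > spontaneous ordering in ≥ 95 % of replicates.
Determinism is bit-level: identical configuration and seed produce
byte-identical epoch-statistics CSVs (fixed row order and float
format). Degenerate inputs have defined behavior throughout: empty
sessions, empty masks, masks off the field of view, zero-variance
frames, unrewarded trials, extreme hit/FA rates, all-artifact pupil
windows and single-trial deduplication all raise typed errors, return
missing values, or skip with a warning as documented on each function.

## Known limitations

Sub-pixel motion, non-rigid deformation and z-drift are out of scope.
The dedup rule's trace-correlation reading (as opposed to per-trial
event coincidence) is not implemented; the agreement threshold and
onset tolerance are configurable if a different reading is wanted.
Cross-animal hypothesis testing is left to standard statistics
libraries on the tidy outputs; the package computes per-session
quantities only, and averaging order across sessions (e.g. of d′
versus its z components) is the caller's choice.
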