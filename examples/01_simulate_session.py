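"""Generate a synthetic go/no-go imaging session with known ground truth.

The generator's defaults emulate an expert session: ~300 trials (40%
catch), 19 axonal ROIs imaged at 30 Hz, per-epoch transient
probabilities of 0.08 (spontaneous), 0.32 (response, HIT trials) and
0.12 (reward), GCaMP6f-like kinetics, plus a pupil trace.
"""

import pomtrace as pt

config = pt.SimConfig(n_trials=100, seed=42)
session = pt.simulate_session(config)

print(f"trials: {len(session.trials)}")
print(session.trials["outcome"].value_counts().to_string())
print(f"ROIs: {session.traces.n_rois}, frames: {session.traces.values.shape[1]} at 30 Hz")
n_injected = len(session.ground_truth.event_table)
print(f"injected transients: {n_injected} "
      f"({n_injected / (config.n_axons * config.n_trials):.2f} per axon-trial)")
print(f"pupil samples: {len(session.pupil.times)} at 15 Hz")

# Every injected event is recorded: these are the validation oracle for
# the detection and epoch-statistics stages.
print("\nfirst injected events (axon 0):")
print(session.ground_truth.event_table.query("axon == 0").head(3).to_string(index=False))
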