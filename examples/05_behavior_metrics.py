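"""Behavioral performance: outcome classification, d-prime, lick metrics.

Outcomes are classified from lick times (HIT/MISS on stimulus trials,
FA/CR on catch trials); session sensitivity is d' = z(H) - z(F) and the
correct fraction (HIT + CR) / all trials, with >= 80% marking expert
performance.  Licking itself should not predict axonal activity: the
rank correlation between per-trial lick rate and the fraction of active
axons stays near zero.
"""

import pomtrace as pt
from pomtrace.pipeline import per_trial_activity

config = pt.SimConfig(n_trials=300, seed=15)
session = pt.simulate_session(config)

trials = pt.classify_outcomes(session.trials.drop(columns="outcome"))
metrics = pt.session_metrics(trials)
print(f"hit rate {metrics.hit_rate:.3f}, FA rate {metrics.fa_rate:.3f}")
print(f"d' = z(H) - z(F) = {metrics.z_hit:.3f} - ({metrics.z_fa:.3f}) = {metrics.d_prime:.3f}")
print(f"correct fraction: {metrics.correct_fraction:.1%} "
      f"({'expert' if metrics.is_expert else 'not expert'} session)")

latency = pt.first_lick_latency(trials[trials.outcome == 'HIT'])
print(f"first-lick latency on HIT trials: {latency.mean():.0f} +- {latency.std():.0f} ms")

# Within HIT trials (fixed outcome), lick vigor does not predict how
# many axons fire: the rank correlation stays near zero.
result = pt.analyze_session(session.traces, trials)
hit_ids = result.trials.loc[result.trials.outcome == "HIT", "trial_id"]
windows = result.windows[result.windows["epoch"] == "response"]
lick_hz = pt.lick_frequency(result.trials, windows).set_index("trial_id")["lick_hz"]
activity = per_trial_activity(result.events, result.tensor.trial_ids, len(result.active_rois))
rho, p = pt.lick_activity_correlation(lick_hz.loc[hit_ids], activity.loc[hit_ids])
print(f"lick-rate vs axon-activity rank correlation (HIT trials): "
      f"rho = {rho:.3f}, p = {p:.3f}")
print("(activity tracks trial outcome, not licking per se)")
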