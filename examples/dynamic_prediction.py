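"""Update one subject's event risk as marker measurements accumulate.

Fits a joint model, then predicts the probability of the event within the
next 0.5 time units at successive landmarks, using only the measurements
collected up to each landmark — the prediction is 'dynamic' because it can
be refreshed whenever a new measurement arrives.
"""

from bsma import builtin_scenario, fit_joint_model, history_at, predict_risk, simulate
from bsma.joint_model import ModelSpec

spec = builtin_scenario("I.1", seed=11, n_subjects=300)
study, _ = simulate(spec)
fit = fit_joint_model(ModelSpec(markers=("m1",), baseline_intervals=1), study)

sid = study.at_risk_ids(1.0)[0]
print(f"subject {sid}: T*={study.subjects.loc[sid, 'time_obs']:.2f}, "
      f"event={study.subjects.loc[sid, 'status']}\n")
print(f"{'landmark s':>10}{'measurements':>14}{'pi(s, 0.5)':>12}{'MC s.e.':>9}")
for s in (0.0, 0.25, 0.5, 0.75, 1.0):
    h = history_at(study, sid, s)
    rp = predict_risk(fit, h, t=0.5, M=300, seed=1)
    print(f"{s:>10.2f}{len(h.long):>14d}{rp.pi_hat:>12.3f}{rp.mc_se:>9.4f}")
print("\npi(s, 0.5) is the probability of the event in (s, s+0.5] given"
      " survival to s and the marker history up to s; the Monte-Carlo"
      " standard error reflects parameter and random-effect uncertainty.")
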