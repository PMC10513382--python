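"""The belief model's reward prediction errors in both Starkweather tasks.

Value weights are fit by LSTD on beliefs from one session and evaluated on
a second. The RPE at reward delivery decreases with reward time when every
trial is rewarded (Task 1) and increases when rewards can be omitted
(Task 2) — the signature pattern of hazard-based timing under partial
observability.
"""

import numpy as np

from beliefrl import value
from beliefrl.experiment import task_beliefs
from beliefrl.tasks import make_config, sample_session

GAMMA = 0.93

for task in ("starkweather1", "starkweather2"):
    cfg = make_config(task)
    fit = sample_session(cfg, 1000, seed=10)
    ev = sample_session(cfg, 1000, seed=11)
    _, traj_fit = task_beliefs(fit)
    _, traj_eval = task_beliefs(ev)
    w = value.lstd_weights(traj_fit.B, value.transition_rewards(fit), GAMMA)
    v = value.value_estimate(traj_eval.B, w)
    trace = value.rpe_trace(ev, v, GAMMA)
    isis, means = value.rpe_by_reward_time(trace, ev)
    print(f"\n{task}: mean RPE at reward delivery by reward time")
    for t, m in zip(isis, means):
        print(f"  ISI {t:2d}  RPE {m:+.3f}")
    print(f"  Spearman trend: {value.reward_time_trend(trace, ev):+.2f}")
    d = trace.delta[~np.isnan(trace.delta)]
    print(f"  mean TD error {d.mean():+.5f} (should be ~0: value is "
          "linear in beliefs)")
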