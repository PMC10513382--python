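"""Train a small Value RNN on Starkweather Task 2 and measure its
belief-likeness.

A GRU is trained end-to-end by semi-gradient TD learning on raw
observations (no belief supervision). Afterwards we ask how much of the
exact belief state can be read out linearly from its activity, and compare
against the same network before training. Sizes here are kept small so the
script runs in a couple of minutes; the full study uses H = 50 units and
10,000 training trials.
"""

import numpy as np

from beliefrl import analysis, rnn, value
from beliefrl.experiment import evaluate_representation, task_beliefs
from beliefrl.tasks import make_config, sample_session

H = 20
cfg = make_config("starkweather2")
train_sess = sample_session(cfg, 4000, seed=0)
init = rnn.init_default(H, seed=1)

tc = rnn.TrainingConfig(max_epochs=60, early_stop_patience=60, seed=1)
model = rnn.train_value_rnn(tc, train_sess, init)
print(f"trained {len(model.train_log)} epochs; "
      f"TD loss {model.train_log[0]:.4f} -> {model.train_log[-1]:.4f}")

fit = sample_session(cfg, 1000, seed=2)
ev = sample_session(cfg, 1000, seed=3)
_, traj_fit = task_beliefs(fit)
_, traj_eval = task_beliefs(ev)
bw = value.lstd_weights(traj_fit.B, value.transition_rewards(fit), 0.93)
ref = value.rpe_trace(ev, value.value_estimate(traj_eval.B, bw), 0.93)

for label, cell in (("trained", model.cell), ("untrained", init)):
    Zf, Ze = rnn.rollout(cell, fit), rnn.rollout(cell, ev)
    m = evaluate_representation(Zf, Ze, fit, ev, traj_fit.B, traj_eval.B,
                                ref, noise_seed=4)
    print(f"{label:10s} belief R^2 {m['belief_r2']:.3f}   "
          f"RPE MSE vs beliefs {m['rpe_mse']:.2e}   "
          f"decoder LL {m['decoder_ll']:.3f} (ceiling {m['belief_ll']:.3f})")
print("training raises the belief R^2 and pushes the RPEs toward the "
      "belief model's.")
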