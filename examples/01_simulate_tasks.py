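"""Simulate the three conditioning tasks and inspect their statistics.

Each session is a 2-channel observation stream (odor cue, reward magnitude)
in 200-ms bins, with hidden microstate labels attached.
"""

import numpy as np

from beliefrl.tasks import make_config, make_probe_session, sample_session

for task in ("starkweather1", "starkweather2", "babayan"):
    cfg = make_config(task)
    s = sample_session(cfg, n_trials=2000, seed=0)
    print(f"{task}: {s.n_trials} trials, {s.n_steps} steps")
    print(f"  mean ITI nulls  {s.itis.mean():6.2f}  (expected 10 + 7 = 17)")
    rewarded = s.reward_times >= 0
    print(f"  rewarded trials {rewarded.mean():6.3f}  "
          f"(expected {1 - cfg.p_omission})")
    print(f"  ISI range       {s.isis[rewarded].min()}..{s.isis[rewarded].max()}")
    if task == "babayan":
        n_blocks = s.trial_blocks.max() + 1
        big = np.array([s.trial_rewards[s.trial_blocks == b].max()
                        for b in range(n_blocks)]) == 10.0
        print(f"  blocks          {n_blocks}, large-reward fraction "
              f"{big.mean():.3f} (expected ~0.5)")

probe = make_probe_session(make_config("babayan"), seed=1)
frac = np.isin(probe.trial_rewards, [1.0, 10.0]).mean()
print(f"\nprobe session: {probe.n_trials} trials, "
      f"{frac:.3f} at standard sizes (rest are intermediate probes)")
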