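"""Exact beliefs and their null-input dynamics in Starkweather Task 2.

The belief is the Bayesian posterior over the 25 microstates. Its only
null-input fixed point is the recurrent ITI state; after an odor the belief
leaves the fixed point and, on an omission trial, must return once the
latest possible reward time (14 steps) has passed.
"""

import numpy as np

from beliefrl.beliefs import (belief_fixed_points, build_starkweather_pomdp,
                              update_belief)
from beliefrl.dynamics import memory_duration

spec = build_starkweather_pomdp(2)
print(f"Task 2 POMDP: K = {spec.K} microstates "
      f"({spec.n_isi} ISI + {spec.K - spec.n_isi} ITI)")
print("reward hazard over the ISI:", np.round(spec.hazard, 3))

fps = belief_fixed_points(spec)
print(f"\nnull-input fixed points: {len(fps)} "
      f"(residual {fps.residuals[0]:.2e})")

step = lambda b: update_belief(spec, b, "null")[0]
odor = lambda b: update_belief(spec, b, "odor")[0]
t = memory_duration(step, odor, spec.b0)
print(f"odor memory of the beliefs: {t} steps "
      "(one step past the 14-step maximum reward delay)")

b = odor(spec.b0)
print("\nsquared distance to the ITI fixed point after an odor:")
for k in range(1, 16):
    d = float(((b - spec.b0) ** 2).sum())
    print(f"  t = {k:2d}   {d:.4f}")
    b = step(b)
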