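# Methods

This note records the models, parameter choices, and numerical conventions
behind `beliefrl`, and what the synthetic tasks do and do not capture.

## Task generative models

Time is discretized into 200-ms bins. Observations are
`o_t = [c_t, r_t]` with a binary odor cue and a nonnegative reward
magnitude; at most one of the two is nonzero in any bin.

Each trial is `[ITI nulls][cue][ISI − 1 nulls][reward]`. The number of ITI
null steps is `min_iti + G` with `min_iti = 10` and `G ~ Geom(p_iti = 1/8)`
supported on {0, 1, 2, ...}, so the minimum reward-to-cue gap is exactly 10
null steps and the mean is 17. The convention matters: it is the one under
which the 11-state ITI chain of the belief model (10 deterministic
microstates plus one recurrent geometric state) exactly matches the
simulator, and it makes the cue emission coincide with leaving the
recurrent ITI state.

* **Starkweather tasks.** Reward delay (ISI) drawn from a discretized
  Gaussian on {6, ..., 14} steps with mean 10 and sd 2.5 — the normal
  density evaluated at the integer support points and renormalized (point
  evaluation, not bin integration; the simplest discretization and an
  explicit assumption). Rewards are unit magnitude. Task 2 omits the
  reward with probability 0.1, i.i.d. per trial (stratification is an
  alternative reading; i.i.d. is assumed). Omission trials end at the cue;
  the hidden state then runs through the ITI chain, so the next cue is at
  least 11 steps away, exactly as in the POMDP.
* **Babayan block task.** ISI uniform on {9, 10, 11}. The reward magnitude
  (1 or 10) is set by a hidden block identity resampled uniformly every 5
  trials. Probe sessions use a fixed block inventory — 39 blocks each of
  r = 1 and r = 10 plus 3 blocks each of r ∈ {2, 4, 6, 8} (90 blocks, 450
  trials, ~87% standard) — shuffled by the session seed.

What the generator does *not* model: continuous time, scalar timing noise,
licking/behavior, action-dependent contingencies, inter-animal variability,
or session-to-session drift. Passing tests therefore show that the
*analyses* behave as designed under the stated task statistics, not that
real neural data would produce the same numbers.

## Microstate POMDPs and beliefs

The semi-Markov tasks are converted to Markov chains over time-indexed
microstates: with maximum ISI `m` and minimum ITI `n`, states `0..m-1`
count time since the odor and states `m..m+n` count time since the reward,
the last being the recurrent geometric ITI state (K = 25 for Starkweather,
22 per block copy for Babayan). Observations are emitted on transitions;
the reward hazard is `h_t = p_t / (1 − F_{t−1})` (exclusive cumulative
mass, so the hazard is exactly 1 at the last possible reward time).

Beliefs follow the transition-emission Bayes filter with explicit
renormalization each step; per-step normalizers (observation likelihoods)
are retained as diagnostics. Conventions:

* Initial belief: one-hot at the recurrent ITI state, the null-input fixed
  point (sessions begin in an ITI).
* **Underflow**: in Task 1 the posterior is undefined once null
  observations continue past the last possible reward time (this cannot
  happen in the training data, only in probe rollouts). If the per-step
  normalizer falls below 1e-12 the belief is reset to the ITI fixed point
  and the step flagged; holding the previous belief is available as an
  option. Under the reset rule Task 1 has a single null-input fixed point,
  matching the finite-omission-duration reading of the task.
* **Babayan blocks**: the block posterior is
  `f(r) = φ(r; 1, σ_r) / (φ(r; 1, σ_r) + φ(r; 10, σ_r))` with σ_r = 0.001,
  evaluated in log space, updated only on nonzero rewards and held
  otherwise — a function of the most recent reward only, not a full filter
  over block history. The 44-dimensional belief is
  `[p_t b^(1), (1 − p_t) b^(2)]` with both block copies propagated by the
  same 22-state POMDP. The first-trial block prior is 1/2; analyses that
  use beliefs as a decoding ceiling exclude each block's first trial,
  where that prior is wrong by construction.

## Value, TD errors, LSTD

All models share the affine readout `V̂_t = wᵀz_t + w₀`. For analysis, the
readout of *every* model (including trained networks) is re-fit in closed
form by LSTD with a constant-1 feature for the intercept, sums restricted
to within-episode transition pairs, and a 1e-8 ridge fallback for singular
systems.

Rewards ride on transitions: the sequence passed to TD/LSTD is
`r[t] = reward observed at step t + 1`, making `δ_t` the prediction error
of the transition `t → t+1` and the "RPE at reward" the δ of the
transition that delivers the reward. With the alternative alignment
(reward paired with the state that already contains it) the belief model's
reward-time RPE is identically ~0 and the tasks' hazard signatures vanish;
the transition alignment is the one under which LSTD-on-beliefs leaves no
systematic TD error and the Task 1 (decreasing) / Task 2 (increasing)
reward-time RPE patterns emerge. The discount is γ = 0.93 per 200-ms bin
throughout, configurable. Omission trials contribute no reward-step RPE
sample; RPE MSE between two models is averaged over rewarded trials only.

## Value RNNs

The recurrent cell is a standard GRU (reset gate applied inside the
candidate, separate input- and hidden-side biases), implemented in numpy.
Training is semi-gradient TD(0): the squared TD error with the
bootstrapped target `r_t + γV̂_{t+1}` treated as a constant is
backpropagated through time over whole episodes (20 trials for
Starkweather, 50 for Babayan, the hidden state reset to zero at each
episode start). The optimizer is Adam (lr 0.003, default moment
parameters); an epoch is one pass over all episodes in randomized batches
of 12; training stops after 150 epochs or 4 consecutive epoch-loss
increases. No hyperparameter search was performed; no gradient clipping is
used. Training arithmetic is single precision (the TD errors are O(1);
double precision changes nothing but time); results are deterministic
given the seeds. Gradients are verified against finite differences of the
detached-target loss, and the cell against an independent scalar
transcription of the gated update.

* **Untrained RNN**: the same cell at its uniform
  U(−1/√H, 1/√H) initialization.
* **Value ESN**: each of the three recurrent gate blocks is an independent
  random orthogonal matrix scaled by a single gain (so every singular
  value equals the gain); input weights uniform with bound √(6/(2+H));
  biases zero. Applying the orthogonal-gain scheme per gate block is an
  interpretive choice (a single 3H×H orthogonal matrix is the
  alternative). The cell is frozen during training. In the sweep
  machinery the ESN readout is fit directly by LSTD — the fixed point that
  gradient TD on frozen features converges to (property-tested) — while
  the gradient path (`freeze_recurrent=True`) remains available.

## Belief-likeness analyses

Each analysis fits on one session and reports on an independent one
(1,000 trials each in the full protocol). Because network activity is a
deterministic function of its inputs, Gaussian noise with per-unit sd
`g σ_i` (g = 0.05, SNR = −20 log₁₀ g ≈ 26 dB) is added to both splits
before every network analysis — regression, decoding, and (by default)
the LSTD value fit as well. The value-fit noise matters: an untrained
reservoir can fit value well through delicate high-gain readouts of its
transient basis, and only under noise does the robustness advantage of
trained features appear in the RPE error (at H = 50 the trained/untrained
RPE-MSE gap is ~200× with noise and ~1× without). A noise-free value fit
is available via `noise_for_value=False`. Exact beliefs are never
noise-injected. Fresh noise is drawn per analysis run from its own seed.

* **Belief R²**: ordinary least squares from the noisy representation
  (plus intercept) to the belief matrix; reported as pooled variance
  explained, `1 − Var(B − ZW)/Var(B)` with `Var(X) = mean_t ‖x_t − x̄‖²`
  — one scalar across all belief dimensions, negative if the fit is worse
  than the mean. The statistic is invariant to invertible affine
  re-parameterizations of the representation.
* **State decoding**: multinomial logistic regression (scikit-learn,
  C = 1, iteration cap 1e4, intercept unpenalized) on per-dimension
  standardized features (fit-split statistics only), scored by the mean
  held-out log-probability of the true microstate. Decoding is at
  microstate resolution; using the beliefs themselves as the decoded
  probabilities is the performance ceiling.
* **Dynamics**: fixed points of the null-input map are found by iterating
  from 20 data-derived seeds (states just after an odor or reward) until
  the consecutive-step squared distance falls below ε = 1e-5, then
  merging points within distance 1e-3 (single-linkage; the cluster
  representative is the member with the smallest residual). With slowly
  contracting networks the raw ε-criterion alone stops well short of the
  attractor, scattering near-duplicate candidates ~0.05 apart; each
  candidate is therefore *polished* by continued iteration (while the
  step size keeps shrinking, up to a cap) so it lands on the attractor it
  was already converging to. Odor/reward memory starts *at* the fixed
  point, applies one observation at t = 1 (odor [1, 0]; reward [0, r] at
  the task's trained magnitude), and reports the first t with squared
  distance to the fixed point below 1e-3; a probe that never leaves has
  memory 1, one that never returns within the step cap gets a sentinel.
  Fixed-point *counts* remain sensitive to training stochasticity and are
  reported but not leaned on; memories are measured from the
  largest-basin point.

## Scaled problem sizes

The exact beliefs, POMDP constructions, LSTD solves, and untrained-network
analyses run at the full published sizes (1,000-trial analysis sessions,
12 replicate initializations, H = 50). Network training in the test suite
uses a scaled-down protocol chosen once — 8,000 training trials, a
90-epoch cap, early-stop patience 8 (epoch losses are noisier with fewer
episodes), 2 replicate seeds per task — as the package's desk-scale
default; the full 10,000-trial / 150-epoch / 12-replicate protocol is the
configured default of the library itself. Known consequence: scaled-down
trained networks sit slightly below fully trained ones on belief R² and
RPE error, and single-replicate statistics are noisier.

## Known limitations

* Fixed-point counting inherits the fragility discussed above; no
  linearization or slow-point analysis is provided.
* The belief filter assumes the exact generative task parameters; no
  model-learning or mismatch analysis.
* The Babayan block posterior deliberately ignores within-block trial
  counting, so it is a ceiling only away from block boundaries.
* Training uses full-episode BPTT; very long episodes (large ITIs) are the
  cost of estimating ITI value correctly, and gradient quality over
  hundreds of steps relies on the GRU's gating alone.
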