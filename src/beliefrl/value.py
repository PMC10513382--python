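"""Linear value estimation and TD-error machinery.

All models in this package (belief model, trained/untrained GRUs, ESNs) use
the same affine value readout ``V_t = w^T z_t + w0`` on top of their
representation ``z_t``. For analysis, the readout weights are fit in closed
form with least-squares TD (LSTD):

    w = D^{-1} d,   D = sum_t z_t (z_t - gamma z_{t+1})^T,   d = sum_t r_t z_t

with sums over ``t = 1..T-1`` within each episode (no cross-boundary pairs)
and a constant-1 feature appended to carry the intercept.

Reward alignment: rewards ride on transitions. The sequence fed to TD and
LSTD is ``r[t] = reward observed at step t+1``, so that the TD error
``delta_t = r_t + gamma V_{t+1} - V_t`` is the prediction error of the
transition from step ``t`` to ``t+1``. The RPE "at the time of reward" on a
trial is the delta of the transition that delivers the reward. (With the
alternative alignment the belief model's reward-time RPE is identically
zero, which contradicts the hazard-driven RPE timing signatures these tasks
are designed to expose.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tasks import Session, OMISSION

__all__ = [
    "ValueWeights",
    "RpeTrace",
    "transition_rewards",
    "lstd_weights",
    "value_estimate",
    "td_errors",
    "rpe_trace",
    "rpe_mse",
    "rpe_by_reward_time",
    "reward_time_trend",
]


@dataclass
class ValueWeights:
    w: np.ndarray
    w0: float
    gamma: float

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.w0):
            raise ValueError("value weights must be finite")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must be in [0, 1)")


def transition_rewards(session: Session) -> np.ndarray:
    """Reward on each transition: ``r[t] = session reward at step t+1``."""
    r = np.zeros(session.n_steps)
    r[:-1] = session.rewards[1:]
    return r


def _episode_pairs(T: int, episode_bounds) -> np.ndarray:
    """Indices t for which (t, t+1) is a valid within-episode pair."""
    if episode_bounds is None:
        episode_bounds = [(0, T)]
    idx = []
    for a, b in episode_bounds:
        if b - a >= 2:
            idx.append(np.arange(a, b - 1))
    if not idx:
        raise ValueError("no valid transition pairs")
    return np.concatenate(idx)


def lstd_weights(Z: np.ndarray, r: np.ndarray, gamma: float,
                 episode_bounds=None, ridge: float = 1e-8) -> ValueWeights:
    """Closed-form LSTD solve for the affine value readout.

    ``Z`` is ``(T, D)``; a constant-1 column is appended internally (it
    carries the intercept ``w0``). ``r[t]`` must be the reward on the
    transition ``t -> t+1``. If the LSTD matrix is singular, a small ridge
    is added to the diagonal and a warning is emitted.
    """
    Z = np.asarray(Z, dtype=float)
    r = np.asarray(r, dtype=float)
    T, D = Z.shape
    if T < D + 2:
        raise ValueError("need at least D + 2 samples")
    idx = _episode_pairs(T, episode_bounds)
    X = np.column_stack([Z, np.ones(T)])
    Zt, Zn = X[idx], X[idx + 1]
    A = Zt.T @ (Zt - gamma * Zn)
    b = Zt.T @ r[idx]
    try:
        sol = np.linalg.solve(A, b)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular LSTD system; solving with ridge fallback")
        sol = np.linalg.solve(A + ridge * np.eye(D + 1), b)
    return ValueWeights(w=sol[:-1], w0=float(sol[-1]), gamma=gamma)


def value_estimate(Z: np.ndarray, weights: ValueWeights) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != weights.w.shape[0]:
        raise ValueError("representation/weight dimension mismatch")
    return Z @ weights.w + weights.w0


def td_errors(values: np.ndarray, r: np.ndarray, gamma: float,
              episode_bounds=None) -> np.ndarray:
    """Per-transition TD errors ``delta_t = r_t + gamma V_{t+1} - V_t``.

    Returns a length ``T - 1`` array; entries for pairs spanning an episode
    boundary are NaN. ``r`` is transition-aligned (see module docstring).
    """
    values = np.asarray(values, dtype=float)
    r = np.asarray(r, dtype=float)
    T = values.shape[0]
    delta = np.full(T - 1, np.nan)
    idx = _episode_pairs(T, episode_bounds)
    idx = idx[idx < T - 1]
    delta[idx] = r[idx] + gamma * values[idx + 1] - values[idx]
    return delta


@dataclass
class RpeTrace:
    """TD errors of one model on one session.

    ``delta[t]`` is the TD error of the transition ``t -> t+1``;
    ``reward_step_delta[i]`` is trial ``i``'s delta at reward delivery
    (NaN on omission trials).
    """

    delta: np.ndarray
    reward_step_delta: np.ndarray


def rpe_trace(session: Session, values: np.ndarray, gamma: float,
              episode_bounds=None) -> RpeTrace:
    """TD errors plus the per-trial RPE at the reward-delivery step."""
    r = transition_rewards(session)
    delta = td_errors(values, r, gamma, episode_bounds=episode_bounds)
    per_trial = np.full(session.n_trials, np.nan)
    for i, rt in enumerate(session.reward_times):
        if rt != OMISSION and rt >= 1:
            per_trial[i] = delta[rt - 1]  # transition delivering the reward
    return RpeTrace(delta=delta, reward_step_delta=per_trial)


def rpe_mse(model_rpe: RpeTrace, reference_rpe: RpeTrace) -> float:
    """Mean squared RPE difference over rewarded trials only."""
    a = model_rpe.reward_step_delta
    b = reference_rpe.reward_step_delta
    if a.shape != b.shape:
        raise ValueError("traces are not from the same session")
    ok = ~np.isnan(a) & ~np.isnan(b)
    if not np.any(ok):
        raise ValueError("no rewarded trials; RPE MSE undefined")
    return float(np.mean((a[ok] - b[ok]) ** 2))


def rpe_by_reward_time(trace: RpeTrace, session: Session):
    """Mean reward-step RPE for each realized reward time (ISI).

    Returns ``(isi_values, mean_rpe)`` over rewarded trials.
    """
    ok = (session.isis != OMISSION) & ~np.isnan(trace.reward_step_delta)
    isis = np.unique(session.isis[ok])
    means = np.array([trace.reward_step_delta[ok & (session.isis == t)].mean()
                      for t in isis])
    return isis, means


def reward_time_trend(trace: RpeTrace, session: Session) -> float:
    """Spearman correlation of mean reward-step RPE with reward time.

    Negative in Starkweather Task 1 (later rewards are better predicted),
    positive in Task 2 (survival past possible omission raises expectancy).
    """
    isis, means = rpe_by_reward_time(trace, session)
    rho, _ = stats.spearmanr(isis, means)
    return float(rho)
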