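"""Microstate POMDPs and exact belief-state computation.

The semi-Markov conditioning tasks are converted to Markov chains over
time-indexed *microstates*. Observations (null / odor / reward) occur on
transitions, so the posterior over states (the *belief*) follows

    b_t(k)  propto  sum_k'  O_o(k, k') T(k, k') b_{t-1}(k'),

renormalized each step, where ``T[to, from]`` is column-stochastic and
``O_o[to, from]`` indicates which observation class each transition emits.

Starkweather construction (0-based indices, K = 25): ISI microstates 0..13
(state ``i`` = ``i+1`` steps since odor), ITI microstates 14..24 with 24 the
recurrent geometric-dwell state. The reward hazard at ISI step ``t`` is
``h_t = p_t / (1 - F_{t-1})`` with ``p`` the ISI distribution and ``F`` its
cumulative mass (so the hazard is 1 at the last possible reward time).

The Babayan task uses two copies of a 22-state block POMDP; the block
posterior ``p_t`` is set by a Gaussian likelihood ratio of the most recent
nonzero reward and held between rewards, and the full 44-dimensional belief
is ``[p_t * b^(1), (1 - p_t) * b^(2)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .tasks import TaskConfig, Session, isi_distribution, make_config

__all__ = [
    "POMDPSpec",
    "BeliefTrajectory",
    "build_starkweather_pomdp",
    "build_babayan_block_pomdp",
    "classify_observation",
    "update_belief",
    "compute_beliefs",
    "block_posterior_from_reward",
    "compute_babayan_beliefs",
    "belief_fixed_points",
]

OBS_CLASSES = ("null", "odor", "reward")

#: per-step likelihoods below this are treated as underflow (belief undefined)
UNDERFLOW_FLOOR = 1e-12


@dataclass
class POMDPSpec:
    """Transition/emission structure of a microstate POMDP.

    ``T_mat[to, from]`` is column-stochastic. ``O[o][to, from]`` is a 0/1
    indicator; summed over the three observation classes it matches the
    support of ``T_mat`` (every possible transition emits exactly one class).
    """

    K: int
    T_mat: np.ndarray
    O: dict
    state_labels: list
    hazard: np.ndarray
    b0: np.ndarray
    _M: dict = field(default_factory=dict, repr=False)

    def M(self, obs: str) -> np.ndarray:
        """Elementwise product ``O_o * T`` used in the belief update."""
        if obs not in self._M:
            self._M[obs] = self.O[obs] * self.T_mat
        return self._M[obs]

    @property
    def n_isi(self) -> int:
        return sum(1 for s in self.state_labels if s.startswith("ISI"))

    def validate(self) -> None:
        np.testing.assert_allclose(self.T_mat.sum(axis=0), 1.0, atol=1e-12)
        support = self.T_mat > 0
        emits = sum(self.O.values()) > 0
        if not np.array_equal(support, emits & support) or np.any(emits & ~support):
            raise ValueError("emission support does not match transition support")
        if abs(self.b0.sum() - 1.0) > 1e-12 or np.any(self.b0 < 0):
            raise ValueError("b0 must lie on the simplex")


def _hazards(probs: np.ndarray) -> np.ndarray:
    """Reward hazard h_t = p_t / (1 - F_{t-1}) over the ISI support."""
    F_prev = np.concatenate([[0.0], np.cumsum(probs)[:-1]])
    surv = 1.0 - F_prev
    if np.any((surv <= 0) & (probs > 0)):
        raise ValueError("hazard undefined: cumulative mass reaches 1 "
                         "before a support point with nonzero mass")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(probs > 0, probs / surv, 0.0)
    h = np.clip(h, 0.0, 1.0)
    if probs[-1] > 0:
        h[-1] = 1.0  # all remaining mass: exact despite cumsum round-off
    return h


def _build_chain_pomdp(isi_support, isi_probs, p_iti, min_iti, p_omission):
    """Shared ISI-chain + ITI-chain construction for both task families."""
    support = np.asarray(isi_support, dtype=int)
    m = int(support.max())            # number of ISI microstates
    K = m + min_iti + 1               # + ITI microstates (min_iti + 1 of them)
    terminal = K - 1

    hazard_full = np.zeros(m)         # hazard indexed by ISI step 1..m -> 0..m-1
    h = _hazards(np.asarray(isi_probs, dtype=float))
    hazard_full[support - 1] = h

    T = np.zeros((K, K))
    O = {o: np.zeros((K, K)) for o in OBS_CLASSES}

    for s in range(m):                # ISI state s = odor was s+1 steps ago
        hz = hazard_full[s]
        if hz > 0:
            T[m, s] = hz              # reward -> first ITI microstate
            O["reward"][m, s] = 1.0
        if s + 1 < m:
            T[s + 1, s] = 1.0 - hz
            O["null"][s + 1, s] = 1.0
        elif hz < 1.0:
            raise ValueError("last ISI microstate must have hazard 1")
    for s in range(m, terminal):      # deterministic ITI chain
        T[s + 1, s] = 1.0
        O["null"][s + 1, s] = 1.0
    T[terminal, terminal] = 1.0 - p_iti
    O["null"][terminal, terminal] = 1.0
    T[0, terminal] = p_iti * (1.0 - p_omission)
    O["odor"][0, terminal] = 1.0
    if p_omission > 0:
        T[m, terminal] = p_iti * p_omission
        O["odor"][m, terminal] = 1.0

    labels = [f"ISI_{i + 1}" for i in range(m)] + \
             [f"ITI_{i + 1}" for i in range(min_iti + 1)]
    b0 = np.zeros(K)
    b0[terminal] = 1.0
    spec = POMDPSpec(K=K, T_mat=T, O=O, state_labels=labels,
                     hazard=hazard_full, b0=b0)
    spec.validate()
    return spec


def build_starkweather_pomdp(task: int | None = None,
                             config: TaskConfig | None = None) -> POMDPSpec:
    """Starkweather microstate POMDP (K = 25: 14 ISI + 11 ITI states).

    Task 1 is the zero-omission special case of the Task 2 construction.
    """
    if config is None:
        if task not in (1, 2):
            raise ValueError("task must be 1 or 2 when no config is given")
        config = make_config(f"starkweather{task}")
    if config.task_id == "babayan":
        raise ValueError("use build_babayan_block_pomdp for the Babayan task")
    return _build_chain_pomdp(config.isi_support, isi_distribution(config),
                              config.p_iti, config.min_iti, config.p_omission)


def build_babayan_block_pomdp(config: TaskConfig | None = None) -> POMDPSpec:
    """Single block-copy of the Babayan POMDP (K = 22: 11 ISI + 11 ITI)."""
    if config is None:
        config = make_config("babayan")
    if config.task_id != "babayan":
        raise ValueError("config must be a Babayan task config")
    return _build_chain_pomdp(config.isi_support, isi_distribution(config),
                              config.p_iti, config.min_iti, 0.0)


def classify_observation(cue: float, reward: float) -> str:
    if cue > 0 and reward > 0:
        raise ValueError("simultaneous cue and reward cannot occur")
    if cue > 0:
        return "odor"
    if reward > 0:
        return "reward"
    return "null"


def update_belief(spec: POMDPSpec, b_prev: np.ndarray, obs: str,
                  underflow: str = "reset"):
    """One Bayes-filter step; returns ``(belief, normalizer)``.

    The normalizer is the likelihood of the observation under the prior
    predictive. If it underflows (e.g. nulls beyond the last possible reward
    time in Task 1, where the posterior is undefined) the belief is reset to
    the ITI fixed point (``underflow="reset"``) or held (``"hold"``); the
    caller can detect this from the returned normalizer.
    """
    u = spec.M(obs) @ b_prev
    norm = float(u.sum())
    if norm < UNDERFLOW_FLOOR:
        if underflow == "reset":
            return spec.b0.copy(), norm
        if underflow == "hold":
            return np.asarray(b_prev, dtype=float).copy(), norm
        raise ValueError(f"unknown underflow rule {underflow!r}")
    return u / norm, norm


@dataclass
class BeliefTrajectory:
    """Time-indexed posterior over microstates.

    ``B[t]`` is the belief after observing ``o_1..o_t``; ``normalizers[t]``
    is the per-step observation likelihood (underflow diagnostics), and
    ``underflow[t]`` flags steps where the posterior was undefined.
    """

    B: np.ndarray
    normalizers: np.ndarray
    underflow: np.ndarray

    @property
    def K(self) -> int:
        return self.B.shape[1]


def compute_beliefs(spec: POMDPSpec, session: Session,
                    underflow: str = "reset") -> BeliefTrajectory:
    """Exact belief trajectory for a session, starting from ``spec.b0``."""
    obs = session.observations
    T = obs.shape[0]
    B = np.empty((T, spec.K))
    norms = np.empty(T)
    b = spec.b0
    for t in range(T):
        o = classify_observation(obs[t, 0], obs[t, 1])
        b, norms[t] = update_belief(spec, b, o, underflow=underflow)
        B[t] = b
    return BeliefTrajectory(B=B, normalizers=norms,
                            underflow=norms < UNDERFLOW_FLOOR)


def block_posterior_from_reward(r: float, mu1: float = 1.0, mu2: float = 10.0,
                                sigma_r: float = 0.001) -> float:
    """P(block 1 | nonzero reward r) from the Gaussian likelihood ratio.

    ``f(r) = phi(r; mu1, sigma) / (phi(r; mu1, sigma) + phi(r; mu2, sigma))``,
    computed in log space; with equal sigmas the crossing point f = 1/2 is at
    the midpoint of the two block means (5.5 for magnitudes 1 and 10).
    """
    return float(expit(((r - mu2) ** 2 - (r - mu1) ** 2) / (2.0 * sigma_r ** 2)))


def compute_babayan_beliefs(spec: POMDPSpec, session: Session,
                            mu1: float = 1.0, mu2: float = 10.0,
                            sigma_r: float = 0.001,
                            p0: float = 0.5) -> BeliefTrajectory:
    """44-dimensional Babayan belief ``[p_t b^(1), (1-p_t) b^(2)]``.

    The block posterior ``p_t`` depends only on the most recent nonzero
    reward (no filtering over block history); both block sub-beliefs are
    propagated with the same per-block POMDP since the within-block trial
    structure is block-independent.
    """
    if session.config.task_id != "babayan":
        raise ValueError("expected a Babayan session")
    obs = session.observations
    T = obs.shape[0]
    B = np.empty((T, 2 * spec.K))
    norms = np.empty(T)
    b1 = spec.b0.copy()
    b2 = spec.b0.copy()
    p = p0
    for t in range(T):
        o = classify_observation(obs[t, 0], obs[t, 1])
        if o == "reward":
            p = block_posterior_from_reward(obs[t, 1], mu1, mu2, sigma_r)
        b1, n1 = update_belief(spec, b1, o)
        b2, n2 = update_belief(spec, b2, o)
        norms[t] = min(n1, n2)
        B[t, :spec.K] = p * b1
        B[t, spec.K:] = (1.0 - p) * b2
    return BeliefTrajectory(B=B, normalizers=norms,
                            underflow=norms < UNDERFLOW_FLOOR)


def belief_fixed_points(spec: POMDPSpec, config=None):
    """Beliefs stable under null observations.

    Candidate seeds are beliefs reached from the initial ITI belief after an
    odor and after each subsequent null, plus post-reward beliefs; each seed
    is iterated under null input (with the underflow-reset rule) and the
    converged points are merged. Returns a :class:`beliefrl.dynamics.FixedPointSet`.
    """
    from .dynamics import DynamicsConfig, find_fixed_points

    if config is None:
        config = DynamicsConfig()
    seeds = []
    b, n = update_belief(spec, spec.b0, "odor")
    if n >= UNDERFLOW_FLOOR:
        seeds.append(b)
        for _ in range(spec.n_isi):
            br, nr = update_belief(spec, b, "reward")
            if nr >= UNDERFLOW_FLOOR:
                seeds.append(br)
            b, n = update_belief(spec, b, "null")
            seeds.append(b)
    step = lambda z: update_belief(spec, z, "null")[0]
    return find_fixed_points(step, seeds[: config.n_seeds], config)
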