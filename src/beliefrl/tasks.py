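"""Synthetic Pavlovian trace-conditioning tasks.

Two task families are implemented, both discretized into 200-ms time bins:

* **Starkweather tasks** (1 and 2): each trial is an intertrial interval (ITI)
  of null observations, a one-step odor cue, an interstimulus interval (ISI)
  drawn from a discretized Gaussian over 6..14 steps, and a unit reward. In
  Task 2 the reward is omitted on 10% of trials, making the post-odor state
  partially observable.
* **Babayan block task**: identical trial skeleton with a uniform ISI over
  {9, 10, 11} steps, but the reward magnitude (1 or 10) is set by a hidden
  block identity resampled uniformly every 5 trials. Probe sessions add
  rare blocks with intermediate magnitudes {2, 4, 6, 8}.

Observations are 2-channel time series ``o_t = [c_t, r_t]`` (binary cue,
reward magnitude). The ITI is parameterized as ``min_iti + Geom(p_iti)``
*null* steps (geometric on {0, 1, 2, ...}), so the minimum number of null
steps separating a reward from the next odor is exactly ``min_iti``.

Hidden states are labeled with the microstate convention of
:mod:`beliefrl.beliefs` (0-based): for a task with maximum ISI ``m`` and
minimum ITI ``n``, states ``0..m-1`` are ISI microstates (state ``i`` means
``i+1`` steps have elapsed since the odor) and states ``m..m+n`` are ITI
microstates, the last of which is the recurrent (geometric-dwell) ITI state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TaskConfig",
    "Session",
    "make_config",
    "isi_distribution",
    "sample_session",
    "make_probe_session",
    "episode_slices",
    "to_episodes",
    "concatenate_episodes",
]

TASK_IDS = ("starkweather1", "starkweather2", "babayan")

#: Sentinel used in per-trial reward-time arrays for omission trials.
OMISSION = -1


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of a conditioning task.

    Defaults are set by :func:`make_config`; this class only validates.
    """

    task_id: str
    p_iti: float = 1.0 / 8.0
    min_iti: int = 10
    isi_support: tuple = (6, 7, 8, 9, 10, 11, 12, 13, 14)
    isi_mean: float = 10.0
    isi_sd: float = 2.5
    p_omission: float = 0.0
    reward_sizes: tuple = (1.0,)
    block_length: int = 5
    time_bin_ms: float = 200.0  # metadata only

    def __post_init__(self):
        if self.task_id not in TASK_IDS:
            raise ValueError(f"unknown task_id {self.task_id!r}")
        if not (0.0 < self.p_iti < 1.0):
            raise ValueError("p_iti must be in (0, 1)")
        if len(self.isi_support) == 0:
            raise ValueError("isi_support must be nonempty")
        support = np.asarray(self.isi_support)
        if support.min() < 1 or np.any(np.diff(support) <= 0):
            raise ValueError("isi_support must be strictly increasing, min >= 1")
        if not (0.0 <= self.p_omission < 1.0):
            raise ValueError("p_omission must be in [0, 1)")
        if any(r <= 0 for r in self.reward_sizes):
            raise ValueError("reward sizes must be positive")
        if self.min_iti < 0 or self.block_length < 1:
            raise ValueError("min_iti must be >= 0 and block_length >= 1")

    @property
    def max_isi(self) -> int:
        return int(max(self.isi_support))

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["isi_support"] = list(self.isi_support)
        d["reward_sizes"] = list(self.reward_sizes)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "TaskConfig":
        d = json.loads(s)
        d["isi_support"] = tuple(d["isi_support"])
        d["reward_sizes"] = tuple(d["reward_sizes"])
        return cls(**d)


def make_config(task_id: str, **overrides) -> TaskConfig:
    """Build the standard configuration for one of the three tasks."""
    if task_id == "starkweather1":
        cfg = TaskConfig(task_id=task_id, p_omission=0.0)
    elif task_id == "starkweather2":
        cfg = TaskConfig(task_id=task_id, p_omission=0.1)
    elif task_id == "babayan":
        cfg = TaskConfig(
            task_id=task_id,
            isi_support=(9, 10, 11),
            reward_sizes=(1.0, 10.0),
            p_omission=0.0,
        )
    else:
        raise ValueError(f"unknown task_id {task_id!r}")
    return replace(cfg, **overrides) if overrides else cfg


def isi_distribution(config: TaskConfig) -> np.ndarray:
    """Probability vector over ``config.isi_support``.

    Starkweather tasks use a discretized Gaussian: the normal density with
    mean ``isi_mean`` and sd ``isi_sd`` evaluated at the integer support
    points and renormalized. The Babayan task uses a uniform distribution.
    """
    support = np.asarray(config.isi_support, dtype=float)
    if support.size == 0:
        raise ValueError("empty ISI support")
    if config.task_id == "babayan":
        return np.full(support.size, 1.0 / support.size)
    dens = stats.norm.pdf(support, loc=config.isi_mean, scale=config.isi_sd)
    return dens / dens.sum()


@dataclass
class Session:
    """A sampled sequence of observations, hidden states and trial metadata.

    ``observations`` is a ``(T, 2)`` array with the binary cue in column 0
    and the reward magnitude in column 1. ``states`` holds the 0-based
    microstate index at every step. Per-trial arrays (``reward_times``,
    ``isis``, ``itis``, ``trial_rewards``, ``trial_blocks``) have length
    ``n_trials``; ``reward_times`` holds the global step index of the reward
    or :data:`OMISSION` on omission trials.
    """

    observations: np.ndarray
    states: np.ndarray
    trial_index: np.ndarray
    block_id: np.ndarray
    reward_times: np.ndarray
    isis: np.ndarray
    itis: np.ndarray
    trial_rewards: np.ndarray
    trial_blocks: np.ndarray
    config: TaskConfig
    seed: int | None = None

    @property
    def n_steps(self) -> int:
        return self.observations.shape[0]

    @property
    def n_trials(self) -> int:
        return int(self.reward_times.shape[0])

    @property
    def cue(self) -> np.ndarray:
        return self.observations[:, 0]

    @property
    def rewards(self) -> np.ndarray:
        return self.observations[:, 1]

    def trial_slices(self) -> list:
        """``(start, stop)`` step indices of each trial."""
        bounds = np.flatnonzero(np.diff(self.trial_index)) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [self.n_steps]])
        return list(zip(starts.tolist(), stops.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(self.n_steps),
                "trial": self.trial_index,
                "block": self.block_id,
                "cue": self.observations[:, 0],
                "reward": self.observations[:, 1],
                "state": self.states,
            }
        )

    def save_csv(self, path) -> None:
        """Columnar CSV plus a JSON sidecar holding config and seed."""
        path = str(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = {"config": json.loads(self.config.to_json()), "seed": self.seed}
        with open(path + ".json", "w") as f:
            json.dump(sidecar, f)

    @classmethod
    def load_csv(cls, path) -> "Session":
        """Inverse of :meth:`save_csv`; per-trial arrays are rebuilt from
        the step-level columns."""
        path = str(path)
        df = pd.read_csv(path)
        with open(path + ".json") as f:
            sidecar = json.load(f)
        config = TaskConfig.from_json(json.dumps(sidecar["config"]))
        trial = df["trial"].to_numpy()
        cue = df["cue"].to_numpy(dtype=float)
        reward = df["reward"].to_numpy(dtype=float)
        n_trials = int(trial.max()) + 1
        reward_times = np.full(n_trials, OMISSION, dtype=int)
        isis = np.full(n_trials, OMISSION, dtype=int)
        itis = np.empty(n_trials, dtype=int)
        trial_rewards = np.zeros(n_trials)
        trial_blocks = np.empty(n_trials, dtype=int)
        for i in range(n_trials):
            steps = np.flatnonzero(trial == i)
            cue_step = steps[np.argmax(cue[steps] > 0)]
            itis[i] = cue_step - steps[0]
            r_steps = steps[reward[steps] > 0]
            if r_steps.size:
                reward_times[i] = r_steps[0]
                isis[i] = r_steps[0] - cue_step
                trial_rewards[i] = reward[r_steps[0]]
            trial_blocks[i] = df["block"].to_numpy()[steps[0]]
        return cls(
            observations=np.column_stack([cue, reward]),
            states=df["state"].to_numpy(dtype=int),
            trial_index=trial,
            block_id=df["block"].to_numpy(dtype=int),
            reward_times=reward_times, isis=isis, itis=itis,
            trial_rewards=trial_rewards, trial_blocks=trial_blocks,
            config=config, seed=sidecar["seed"])


def _trial_states(iti_nulls: int, isi: int, omitted: bool, config: TaskConfig,
                  first_trial: bool) -> np.ndarray:
    """Microstate labels for one trial (block-local for Babayan)."""
    m = config.max_isi              # number of ISI microstates
    terminal = m + config.min_iti   # recurrent ITI state index
    if first_trial:
        iti_states = np.full(iti_nulls, terminal, dtype=int)
    else:
        # previous step was the reward (state m) or the omission cue (state m)
        iti_states = np.minimum(m + np.arange(1, iti_nulls + 1), terminal)
    if omitted:
        # odor transitions straight into the first ITI microstate
        return np.concatenate([iti_states, [m]])
    isi_states = np.arange(isi)     # cue step is ISI state 0
    return np.concatenate([iti_states, isi_states, [m]])


def _generate(config: TaskConfig, n_trials: int, seed: int,
              block_rewards: np.ndarray | None = None) -> Session:
    rng = np.random.default_rng(seed)
    p_isi = isi_distribution(config)
    support = np.asarray(config.isi_support)
    babayan = config.task_id == "babayan"

    if babayan:
        if block_rewards is None:
            n_blocks = int(np.ceil(n_trials / config.block_length))
            block_rewards = rng.choice(config.reward_sizes, size=n_blocks)
        else:
            block_rewards = np.asarray(block_rewards, dtype=float)
            n_trials = block_rewards.size * config.block_length

    obs_parts, state_parts = [], []
    trial_index, block_id = [], []
    reward_times = np.empty(n_trials, dtype=int)
    isis = np.empty(n_trials, dtype=int)
    itis = np.empty(n_trials, dtype=int)
    trial_rewards = np.empty(n_trials, dtype=float)
    trial_blocks = np.empty(n_trials, dtype=int)

    t = 0
    for trial in range(n_trials):
        iti_nulls = config.min_iti + int(rng.geometric(config.p_iti)) - 1
        isi = int(rng.choice(support, p=p_isi))
        omitted = bool(rng.random() < config.p_omission)
        if babayan:
            block = trial // config.block_length
            r = float(block_rewards[block])
        else:
            block = 0
            r = float(config.reward_sizes[0])

        n = iti_nulls + 1 if omitted else iti_nulls + 1 + isi
        obs = np.zeros((n, 2))
        obs[iti_nulls, 0] = 1.0  # cue
        if not omitted:
            obs[-1, 1] = r

        states = _trial_states(iti_nulls, isi, omitted, config, trial == 0)
        if babayan:
            # block-local states offset by 0 or K_block; probe blocks with
            # intermediate magnitudes are labeled by the nearest block mean
            ident = 0 if r < 5.5 else 1
            states = states + ident * (config.max_isi + config.min_iti + 1)

        obs_parts.append(obs)
        state_parts.append(states)
        trial_index.append(np.full(n, trial))
        block_id.append(np.full(n, block))
        reward_times[trial] = OMISSION if omitted else t + n - 1
        isis[trial] = isi if not omitted else OMISSION
        itis[trial] = iti_nulls
        trial_rewards[trial] = 0.0 if omitted else r
        trial_blocks[trial] = block
        t += n

    return Session(
        observations=np.concatenate(obs_parts),
        states=np.concatenate(state_parts),
        trial_index=np.concatenate(trial_index),
        block_id=np.concatenate(block_id),
        reward_times=reward_times,
        isis=isis,
        itis=itis,
        trial_rewards=trial_rewards,
        trial_blocks=trial_blocks,
        config=config,
        seed=seed,
    )


def sample_session(config: TaskConfig, n_trials: int, seed: int) -> Session:
    """Sample ``n_trials`` trials of the configured task.

    Each trial is ``[iti_nulls][cue][isi - 1 nulls][reward]``, where
    ``iti_nulls = min_iti + Geom(p_iti)`` with the geometric on {0, 1, ...}.
    Omission trials (Starkweather Task 2) end at the cue step. For the
    Babayan task the block reward magnitude is resampled uniformly every
    ``block_length`` trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    return _generate(config, n_trials, int(seed))


#: Block composition of the probe sessions with intermediate reward sizes:
#: 39 blocks each of r=1 and r=10, 3 blocks each of r in {2, 4, 6, 8}.
PROBE_PRESET_S2 = {1.0: 39, 10.0: 39, 2.0: 3, 4.0: 3, 6.0: 3, 8.0: 3}


def make_probe_session(config: TaskConfig, seed: int,
                       block_counts: dict | None = None) -> Session:
    """Babayan session with rare intermediate-reward probe blocks.

    ``block_counts`` maps reward magnitude to number of blocks; the default
    preset has 84 blocks (420 trials), with ~93% of trials at r in {1, 10}.
    Block order is shuffled. Passing counts with only magnitudes {1, 10}
    reduces to the law of :func:`sample_session`.
    """
    if config.task_id != "babayan":
        raise ValueError("probe sessions are defined for the Babayan task only")
    if block_counts is None:
        block_counts = PROBE_PRESET_S2
    rewards = np.concatenate([np.full(n, r) for r, n in block_counts.items()])
    rng = np.random.default_rng(seed)
    rng.shuffle(rewards)
    # offset the generator seed so trial timing differs from sample_session
    return _generate(config, rewards.size * config.block_length,
                     int(seed), block_rewards=rewards)


def episode_slices(session: Session, episode_len_trials: int) -> list:
    """``(start, stop)`` step ranges of consecutive ``episode_len_trials``-trial
    episodes; a trailing remainder of trials is dropped."""
    if episode_len_trials < 1:
        raise ValueError("episode length must be >= 1")
    if episode_len_trials > session.n_trials:
        raise ValueError("episode longer than session")
    trial_bounds = session.trial_slices()
    n_ep = session.n_trials // episode_len_trials
    out = []
    for e in range(n_ep):
        start = trial_bounds[e * episode_len_trials][0]
        stop = trial_bounds[(e + 1) * episode_len_trials - 1][1]
        out.append((start, stop))
    return out


def to_episodes(session: Session, episode_len_trials: int) -> list:
    """Observation segments of consecutive episodes (see :func:`episode_slices`)."""
    return [session.observations[a:b] for a, b in
            episode_slices(session, episode_len_trials)]


def concatenate_episodes(episodes: list) -> np.ndarray:
    return np.concatenate(episodes, axis=0)
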