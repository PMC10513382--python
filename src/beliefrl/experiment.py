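"""Experiment orchestration: model evaluation pipeline, sweeps, summaries.

The canonical evaluation of any model (belief model, Value RNN, Untrained
RNN, Value ESN) uses two independent sessions of the same task: a *fit*
session for every fitted quantity (LSTD value weights, belief-regression
weights, state-decoder weights) and an *eval* session for every reported
number. Per model the report row contains:

``rpe_mse``       mean squared difference from the belief model's RPEs at
                  reward delivery, on the eval session;
``belief_r2``     held-out pooled variance of beliefs explained by an affine
                  readout of the (noise-injected) representation;
``decoder_ll``    held-out mean log-likelihood of the true microstate under
                  a multinomial decoder of the (noise-injected) representation;
``belief_ll``     the belief ceiling for ``decoder_ll``;
``n_fixed_points``, ``odor_memory``, ``reward_memory``, ``memory_diff``
                  null-input dynamics statistics.

Noise is applied only for regression/decoding, not for value fitting.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import analysis, beliefs, dynamics, rnn, tasks, value

__all__ = [
    "derive_seed",
    "task_beliefs",
    "babayan_eval_mask",
    "observation_following_states",
    "model_dynamics",
    "evaluate_representation",
    "ExperimentGrid",
    "run_grid",
    "summarize",
]


def derive_seed(base_seed: int, *parts) -> int:
    """Deterministic per-cell seed from a base seed and provenance tags."""
    key = repr((int(base_seed),) + tuple(parts)).encode()
    return zlib.crc32(key) % (2 ** 31)


def task_beliefs(session: tasks.Session):
    """POMDP spec and exact belief trajectory for a session of any task."""
    cfg = session.config
    if cfg.task_id == "babayan":
        spec = beliefs.build_babayan_block_pomdp(cfg)
        traj = beliefs.compute_babayan_beliefs(spec, session)
    else:
        spec = beliefs.build_starkweather_pomdp(config=cfg)
        traj = beliefs.compute_beliefs(spec, session)
    return spec, traj


def babayan_eval_mask(session: tasks.Session) -> np.ndarray:
    """Steps belonging to any trial except the first of its block.

    The block posterior is defined from the most recent reward only, so the
    beliefs are a decoding ceiling only once a reward of the current block
    has been seen.
    """
    first = np.zeros(session.n_trials, dtype=bool)
    first[0] = True
    first[1:] = session.trial_blocks[1:] != session.trial_blocks[:-1]
    return ~first[session.trial_index]


def observation_following_states(Z: np.ndarray, session: tasks.Session,
                                 n: int, seed: int) -> list:
    """``n`` random representation states taken just after an odor or
    reward observation (the seed states for fixed-point searches)."""
    idx = np.flatnonzero((session.cue > 0) | (session.rewards > 0))
    rng = np.random.default_rng(seed)
    pick = rng.choice(idx, size=min(n, idx.size), replace=False)
    return [Z[t] for t in pick]


def model_dynamics(model: rnn.RecurrentValueModel, Z: np.ndarray,
                   session: tasks.Session,
                   config: dynamics.DynamicsConfig | None = None,
                   reward_size: float | None = None) -> dict:
    """Fixed points and odor/reward memories of a recurrent value model.

    Memories are measured from the fixed point with the largest basin
    (models with several fixed points are flagged via ``n_fixed_points``).
    The reward probe uses the task's trained reward magnitude by default.
    """
    if config is None:
        config = dynamics.DynamicsConfig()
    if reward_size is None:
        reward_size = float(session.config.reward_sizes[0])
    cell = model.cell
    null = np.zeros(2)
    step = lambda z: rnn.gru_step(cell, z, null)
    seeds = observation_following_states(
        Z, session, config.n_seeds,
        derive_seed(model.seed or 0, "fp_seeds"))
    fps = dynamics.find_fixed_points(step, seeds, config)
    out = {"n_fixed_points": len(fps), "fp_n_failed": fps.n_failed}
    if len(fps) == 0:
        out.update(odor_memory=np.nan, reward_memory=np.nan,
                   memory_diff=np.nan)
        return out
    z0 = fps.points[0]
    odor = lambda z: rnn.gru_step(cell, z, np.array([1.0, 0.0]))
    rew = lambda z: rnn.gru_step(cell, z, np.array([0.0, reward_size]))
    out.update(dynamics.memory_difference(step, odor, rew, z0, config))
    return out


def evaluate_representation(Z_fit: np.ndarray, Z_eval: np.ndarray,
                            fit_session: tasks.Session,
                            eval_session: tasks.Session,
                            B_fit: np.ndarray, B_eval: np.ndarray,
                            reference_rpe: value.RpeTrace,
                            gamma: float = 0.93, g: float = 0.05,
                            noise_seed: int = 0,
                            n_states: int | None = None,
                            noise_for_value: bool = True) -> dict:
    """Statistical belief-likeness metrics for one representation.

    Noise is injected into both splits before every fit, including the
    LSTD value fit (``noise_for_value=False`` restricts it to regression
    and decoding). Fitting values on the noisy representation is what
    separates trained networks (robust features) from untrained reservoirs
    (fragile high-gain readouts) in RPE error.
    """
    Zf = analysis.add_representation_noise(
        Z_fit, analysis.NoiseConfig(g=g, seed=derive_seed(noise_seed, "fit")))
    Ze = analysis.add_representation_noise(
        Z_eval, analysis.NoiseConfig(g=g, seed=derive_seed(noise_seed, "eval")))

    Zf_v, Ze_v = (Zf, Ze) if noise_for_value else (Z_fit, Z_eval)
    w = value.lstd_weights(Zf_v, value.transition_rewards(fit_session), gamma)
    v_eval = value.value_estimate(Ze_v, w)
    trace = value.rpe_trace(eval_session, v_eval, gamma)
    out = {"rpe_mse": value.rpe_mse(trace, reference_rpe)}

    out["belief_r2"] = analysis.belief_r2(Zf, B_fit, Ze, B_eval)

    if n_states is None:
        n_states = B_fit.shape[1]
    mask = babayan_eval_mask(eval_session) \
        if eval_session.config.task_id == "babayan" else None
    dec = analysis.fit_state_decoder(Zf, fit_session.states, n_states=n_states)
    out["decoder_ll"] = analysis.decoder_loglik(dec, Ze, eval_session.states,
                                                sample_mask=mask)
    out["belief_ll"] = analysis.belief_loglik(B_eval, eval_session.states,
                                              sample_mask=mask)
    return out


@dataclass(frozen=True)
class ExperimentGrid:
    """A sweep over tasks, model kinds, capacities and gains.

    ``kinds`` may contain ``"value_rnn"``, ``"untrained"``, and ``"esn"``;
    ESN cells take their capacity from ``hidden_sizes`` and sweep ``gains``
    (their readout is fit in closed form by LSTD, the solution gradient TD
    converges to). Replicates differ in both the parameter seed and, for
    trained cells, the training-session realization.
    """

    tasks: tuple = ("starkweather2",)
    kinds: tuple = ("untrained",)
    hidden_sizes: tuple = (50,)
    gains: tuple = (1.9,)
    g: float = 0.05
    n_replicates: int = 12
    base_seed: int = 0
    n_train_trials: int = 10_000
    n_analysis_trials: int = 1_000
    train_config: rnn.TrainingConfig = field(default_factory=rnn.TrainingConfig)
    dynamics_config: dynamics.DynamicsConfig = \
        field(default_factory=dynamics.DynamicsConfig)
    compute_dynamics: bool = True


def _make_model(kind: str, task_id: str, H: int, gain: float, seed: int,
                grid: ExperimentGrid) -> rnn.RecurrentValueModel:
    gamma = grid.train_config.gamma
    if kind == "untrained":
        cell = rnn.init_default(H, seed)
        zero = value.ValueWeights(np.zeros(H), 0.0, gamma)
        return rnn.RecurrentValueModel(cell, zero, "untrained", seed=seed)
    if kind == "esn":
        cell = rnn.init_esn(H, gain, seed)
        zero = value.ValueWeights(np.zeros(H), 0.0, gamma)
        return rnn.RecurrentValueModel(cell, zero, f"esn(gain={gain})",
                                       seed=seed)
    if kind == "value_rnn":
        cfg = tasks.make_config(task_id)
        train_sess = tasks.sample_session(
            cfg, grid.n_train_trials, derive_seed(seed, "train_session"))
        init = rnn.init_default(H, seed)
        tc = replace(grid.train_config, seed=seed)
        return rnn.train_value_rnn(tc, train_sess, init)
    raise ValueError(f"unknown model kind {kind!r}")


def run_grid(grid: ExperimentGrid) -> pd.DataFrame:
    """Execute simulate -> (train) -> analyze for every grid cell.

    One row per (task, kind, H, gain, replicate); failures are recorded as
    rows with an ``error`` field and do not stop the sweep. Deterministic
    given ``base_seed``.
    """
    rows = []
    for task_id in grid.tasks:
        cfg = tasks.make_config(task_id)
        fit_sess = tasks.sample_session(
            cfg, grid.n_analysis_trials,
            derive_seed(grid.base_seed, task_id, "fit"))
        eval_sess = tasks.sample_session(
            cfg, grid.n_analysis_trials,
            derive_seed(grid.base_seed, task_id, "eval"))
        _, traj_fit = task_beliefs(fit_sess)
        _, traj_eval = task_beliefs(eval_sess)
        gamma = grid.train_config.gamma
        bw = value.lstd_weights(traj_fit.B, value.transition_rewards(fit_sess),
                                gamma)
        ref_rpe = value.rpe_trace(
            eval_sess, value.value_estimate(traj_eval.B, bw), gamma)
        for kind in grid.kinds:
            gains = grid.gains if kind == "esn" else (np.nan,)
            for H in grid.hidden_sizes:
                for gain in gains:
                    for rep in range(grid.n_replicates):
                        seed = derive_seed(grid.base_seed, task_id, kind,
                                           H, gain, rep)
                        row = {"task": task_id, "kind": kind, "H": H,
                               "gain": gain, "replicate": rep, "seed": seed}
                        try:
                            model = _make_model(kind, task_id, H, gain,
                                                seed, grid)
                            Zf = rnn.rollout(model.cell, fit_sess)
                            Ze = rnn.rollout(model.cell, eval_sess)
                            row.update(evaluate_representation(
                                Zf, Ze, fit_sess, eval_sess,
                                traj_fit.B, traj_eval.B, ref_rpe,
                                gamma=gamma, g=grid.g, noise_seed=seed))
                            if grid.compute_dynamics:
                                row.update(model_dynamics(
                                    model, Ze, eval_sess,
                                    grid.dynamics_config))
                            row["train_epochs"] = len(model.train_log)
                        except Exception as e:  # pragma: no cover
                            row["error"] = repr(e)
                        rows.append(row)
    return pd.DataFrame(rows)


def summarize(report: pd.DataFrame) -> pd.DataFrame:
    """Median/mean/SE of each metric per grid cell, with replicate counts."""
    if report.empty:
        raise ValueError("empty report")
    metrics = [c for c in ("rpe_mse", "belief_r2", "decoder_ll", "belief_ll",
                           "odor_memory", "reward_memory", "memory_diff",
                           "n_fixed_points") if c in report.columns]
    ok = report[report.get("error").isna()] if "error" in report.columns \
        else report
    grp = ok.groupby(["task", "kind", "H", "gain"], dropna=False)
    out = []
    for keys, sub in grp:
        row = dict(zip(["task", "kind", "H", "gain"], keys))
        row["n"] = len(sub)
        for m in metrics:
            vals = sub[m].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            row[f"{m}_median"] = float(np.median(vals))
            row[f"{m}_mean"] = float(np.mean(vals))
            row[f"{m}_se"] = float(vals.std(ddof=1) / np.sqrt(vals.size)) \
                if vals.size > 1 else np.nan
        out.append(row)
    return pd.DataFrame(out)
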