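"""Recurrent value models: GRU cell, TD training, and reservoir variants.

A *Value RNN* is a gated recurrent unit (GRU) whose hidden state feeds an
affine value readout ``V_t = w^T z_t + w0``. The full parameter vector
(recurrent cell + readout) is trained by semi-gradient TD(0): the squared
TD error ``(r_t + gamma V_{t+1} - V_t)^2`` is backpropagated through time
with the bootstrapped target treated as a constant. An *Untrained RNN* is
the same network at initialization; a *Value ESN* keeps the (orthogonally
initialized, gain-scaled) cell frozen and learns only the readout.

The cell follows the standard GRU equations with the reset gate applied
inside the candidate (the convention of the common deep-learning GRU
implementations, including the separate hidden-side candidate bias):

    r = sigmoid(W_ir o + b_ir + W_hr z + b_hr)
    u = sigmoid(W_iz o + b_iz + W_hz z + b_hz)
    n = tanh(W_in o + b_in + r * (W_hn z + b_hn))
    z' = (1 - u) * n + u * z

Everything here is plain numpy; training is exactly reproducible given the
seeds. Gate blocks are stored stacked row-wise in order (reset, update,
candidate), mirroring the usual ``(3H, .)`` weight layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .tasks import Session, episode_slices
from .value import ValueWeights

__all__ = [
    "GruParams",
    "TrainingConfig",
    "RecurrentValueModel",
    "gru_step",
    "rollout",
    "init_default",
    "init_esn",
    "train_value_rnn",
    "save_model",
    "load_model",
]

N_INPUTS = 2  # [cue, reward]


@dataclass
class GruParams:
    """GRU cell parameters; gate blocks stacked as (reset, update, candidate)."""

    W_i: np.ndarray  # (3H, 2) input weights
    W_h: np.ndarray  # (3H, H) recurrent weights
    b_i: np.ndarray  # (3H,) input-side biases
    b_h: np.ndarray  # (3H,) hidden-side biases

    def __post_init__(self):
        H = self.H
        if self.W_i.shape != (3 * H, N_INPUTS) or self.W_h.shape != (3 * H, H) \
                or self.b_i.shape != (3 * H,) or self.b_h.shape != (3 * H,):
            raise ValueError("inconsistent GRU parameter shapes")
        for a in (self.W_i, self.W_h, self.b_i, self.b_h):
            if not np.all(np.isfinite(a)):
                raise ValueError("GRU parameters must be finite")

    @property
    def H(self) -> int:
        return self.W_h.shape[1]

    def gate_block(self, which: str, kind: str = "recurrent") -> np.ndarray:
        i = ("reset", "update", "candidate").index(which)
        H = self.H
        m = self.W_h if kind == "recurrent" else self.W_i
        return m[i * H:(i + 1) * H]

    def copy(self) -> "GruParams":
        return GruParams(self.W_i.copy(), self.W_h.copy(),
                         self.b_i.copy(), self.b_h.copy())

    def digest(self) -> int:
        """Order-stable content hash (used to verify freeze contracts)."""
        h = 0
        for a in (self.W_i, self.W_h, self.b_i, self.b_h):
            h ^= hash(a.tobytes())
        return h


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def gru_step(params: GruParams, z_prev: np.ndarray, o: np.ndarray) -> np.ndarray:
    """One GRU update; accepts a single state ``(H,)`` or a batch ``(B, H)``."""
    z_prev = np.asarray(z_prev, dtype=float)
    o = np.asarray(o, dtype=float)
    if not (np.all(np.isfinite(z_prev)) and np.all(np.isfinite(o))):
        raise ValueError("non-finite inputs to gru_step")
    H = params.H
    gi = o @ params.W_i.T + params.b_i
    gh = z_prev @ params.W_h.T + params.b_h
    r = _sigmoid(gi[..., :H] + gh[..., :H])
    u = _sigmoid(gi[..., H:2 * H] + gh[..., H:2 * H])
    n = np.tanh(gi[..., 2 * H:] + r * gh[..., 2 * H:])
    return (1.0 - u) * n + u * z_prev


def rollout(params: GruParams, observations: np.ndarray,
            z0: np.ndarray | None = None, episode_bounds=None) -> np.ndarray:
    """Hidden-state trajectory ``Z`` (T, H) driven by an observation stream.

    The state is reset to ``z0`` (zeros by default) at the start of each
    episode; with no bounds the whole stream is one episode. Deterministic.
    """
    if isinstance(observations, Session):
        observations = observations.observations
    obs = np.asarray(observations, dtype=float)
    T = obs.shape[0]
    H = params.H
    if z0 is None:
        z0 = np.zeros(H)
    if episode_bounds is None:
        episode_bounds = [(0, T)]
    Z = np.empty((T, H))
    for a, b in episode_bounds:
        z = z0
        for t in range(a, b):
            z = gru_step(params, z, obs[t])
            Z[t] = z
    return Z


def init_default(H: int, seed: int) -> GruParams:
    """Uniform initialization on ``(-1/sqrt(H), 1/sqrt(H))`` for every
    weight and bias (the customary default for GRU layers)."""
    if H < 1:
        raise ValueError("H must be >= 1")
    rng = np.random.default_rng(seed)
    a = 1.0 / np.sqrt(H)
    u = lambda *shape: rng.uniform(-a, a, size=shape)
    return GruParams(W_i=u(3 * H, N_INPUTS), W_h=u(3 * H, H),
                     b_i=u(3 * H), b_h=u(3 * H))


def _random_orthogonal(H: int, rng) -> np.ndarray:
    """Haar-ish orthogonal matrix via sign-corrected QR of a Gaussian."""
    q, r = np.linalg.qr(rng.standard_normal((H, H)))
    return q * np.sign(np.diag(r))


def init_esn(H: int, gain: float, seed: int) -> GruParams:
    """Echo-state initialization: each recurrent gate block is an independent
    random orthogonal matrix scaled by ``gain`` (so all its singular values
    equal the gain); input weights are uniform on ``(-a, a)`` with
    ``a = sqrt(6 / (2 + H))``; all biases are zero. The gain sets the
    duration of the network's transient response to an input."""
    if H < 1:
        raise ValueError("H must be >= 1")
    if not np.isfinite(gain) or gain <= 0:
        raise ValueError("gain must be a positive real")
    rng = np.random.default_rng(seed)
    W_h = gain * np.concatenate([_random_orthogonal(H, rng) for _ in range(3)])
    a = np.sqrt(6.0 / (N_INPUTS + H))
    W_i = rng.uniform(-a, a, size=(3 * H, N_INPUTS))
    return GruParams(W_i=W_i, W_h=W_h,
                     b_i=np.zeros(3 * H), b_h=np.zeros(3 * H))


@dataclass(frozen=True)
class TrainingConfig:
    """Semi-gradient TD training protocol.

    Defaults: Adam with learning rate 0.003, at most 150 epochs over a
    10,000-trial session split into 20-trial (Starkweather) or 50-trial
    (Babayan) episodes, batches of 12 episodes, early stop after 4
    consecutive epoch-loss increases, discount gamma = 0.93 per 200-ms bin.
    """

    lr: float = 0.003
    max_epochs: int = 150
    batch_size: int = 12
    early_stop_patience: int = 4
    episode_len: int | None = None  # derived from the task if None
    gamma: float = 0.93
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.lr <= 0 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("lr, max_epochs, batch_size must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")

    def resolved_episode_len(self, task_id: str) -> int:
        if self.episode_len is not None:
            return self.episode_len
        return 50 if task_id == "babayan" else 20


@dataclass
class RecurrentValueModel:
    """A GRU cell plus affine value readout, with training provenance."""

    cell: GruParams
    readout: ValueWeights
    provenance: str  # "value_rnn" | "untrained" | "esn(gain=..)"
    train_log: list = field(default_factory=list)
    seed: int | None = None

    @property
    def H(self) -> int:
        return self.cell.H

    def values(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.readout.w + self.readout.w0


# ---------------------------------------------------------------------------
# batched BPTT machinery
#
# The numpy implementations below are the reference; jitted kernels (used
# automatically when numba is importable) compute the identical quantities
# and are equivalence-tested against them.

try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _bwd_kernel(X, W_h, dH, Hp, Rr, Uu, Nn, HN,
                    gWi, gWh, gbi, gbh):
        B, T, _ = X.shape
        H = W_h.shape[1]
        dh_next = np.zeros((B, H), dtype=X.dtype)
        d_gi = np.empty((B, 3 * H), dtype=X.dtype)
        d_gh = np.empty((B, 3 * H), dtype=X.dtype)
        for t in range(T - 1, -1, -1):
            for i in range(B):
                for j in range(H):
                    h_prev = Hp[i, t, j]
                    r = Rr[i, t, j]
                    u = Uu[i, t, j]
                    n = Nn[i, t, j]
                    hn = HN[i, t, j]
                    dh = dH[i, t, j] + dh_next[i, j]
                    du = dh * (h_prev - n)
                    dn_pre = dh * (1.0 - u) * (1.0 - n * n)
                    dr_pre = dn_pre * hn * r * (1.0 - r)
                    du_pre = du * u * (1.0 - u)
                    d_gi[i, j] = dr_pre
                    d_gi[i, H + j] = du_pre
                    d_gi[i, 2 * H + j] = dn_pre
                    d_gh[i, j] = dr_pre
                    d_gh[i, H + j] = du_pre
                    d_gh[i, 2 * H + j] = dn_pre * r
                    dh_next[i, j] = dh * u
            gWi += np.dot(d_gi.T, X[:, t].copy())
            gWh += np.dot(d_gh.T, Hp[:, t].copy())
            for k in range(3 * H):
                for i in range(B):
                    gbi[k] += d_gi[i, k]
                    gbh[k] += d_gh[i, k]
            dh_next += np.dot(d_gh, W_h)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _forward_batch(params: GruParams, X: np.ndarray):
    """Forward pass over a padded batch ``X`` (B, T, 2); returns hidden
    states (B, T, H) and stacked caches ``(Hp, r, u, n, hn)`` for BPTT."""
    B, T, _ = X.shape
    H = params.H
    dt = X.dtype
    W_hT = np.ascontiguousarray(params.W_h.T, dtype=dt)
    b_h = params.b_h.astype(dt)
    GI = X @ params.W_i.T.astype(dt) + params.b_i.astype(dt)  # (B, T, 3H)
    Hs = np.empty((B, T, H), dtype=dt)
    Hp, Rr, Uu, Nn, HN = (np.empty((B, T, H), dtype=dt) for _ in range(5))
    h = np.zeros((B, H), dtype=dt)
    for t in range(T):
        gh = h @ W_hT + b_h
        g = GI[:, t] + gh
        ru = _sigmoid(g[:, :2 * H])      # reset and update gates together
        r, u = ru[:, :H], ru[:, H:]
        hn = gh[:, 2 * H:]
        n = np.tanh(GI[:, t, 2 * H:] + r * hn)
        h_new = (1.0 - u) * n + u * h
        Hp[:, t] = h
        Rr[:, t] = r
        Uu[:, t] = u
        Nn[:, t] = n
        HN[:, t] = hn
        Hs[:, t] = h_new
        h = h_new
    return Hs, (Hp, Rr, Uu, Nn, HN)


def _grad_arrays(params: GruParams, dt):
    return {"W_i": np.zeros(params.W_i.shape, dtype=dt),
            "W_h": np.zeros(params.W_h.shape, dtype=dt),
            "b_i": np.zeros(params.b_i.shape, dtype=dt),
            "b_h": np.zeros(params.b_h.shape, dtype=dt)}


def _backward_batch(params: GruParams, X: np.ndarray, cache, dH: np.ndarray):
    """BPTT given per-step hidden-state gradients ``dH`` (B, T, H)."""
    B, T, _ = X.shape
    H = params.H
    dt = X.dtype
    W_h = params.W_h.astype(dt)
    Hp, Rr, Uu, Nn, HN = cache
    g = _grad_arrays(params, dt)
    dh_next = np.zeros((B, H), dtype=dt)
    d_gi = np.empty((B, 3 * H), dtype=dt)
    d_gh = np.empty((B, 3 * H), dtype=dt)
    for t in range(T - 1, -1, -1):
        h_prev, r, u, n, hn = Hp[:, t], Rr[:, t], Uu[:, t], Nn[:, t], HN[:, t]
        dh = dH[:, t] + dh_next
        du = dh * (h_prev - n)
        dn_pre = dh * (1.0 - u) * (1.0 - n * n)
        dr_pre = dn_pre * hn * r * (1.0 - r)
        du_pre = du * u * (1.0 - u)
        d_gi[:, :H] = dr_pre
        d_gi[:, H:2 * H] = du_pre
        d_gi[:, 2 * H:] = dn_pre
        d_gh[:, :2 * H] = d_gi[:, :2 * H]
        d_gh[:, 2 * H:] = dn_pre * r
        g["W_i"] += d_gi.T @ X[:, t]
        g["W_h"] += d_gh.T @ h_prev
        g["b_i"] += d_gi.sum(axis=0)
        g["b_h"] += d_gh.sum(axis=0)
        dh_next = dh * u + d_gh @ W_h
    return g


def _backward_batch_fast(params: GruParams, X: np.ndarray, cache, dH):
    """Jitted BPTT; bit-compatible with :func:`_backward_batch`."""
    Hp, Rr, Uu, Nn, HN = cache
    dt = X.dtype
    g = _grad_arrays(params, dt)
    _bwd_kernel(np.ascontiguousarray(X), params.W_h.astype(dt),
                np.ascontiguousarray(dH), Hp, Rr, Uu, Nn, HN,
                g["W_i"], g["W_h"], g["b_i"], g["b_h"])
    return g


class _Adam:
    def __init__(self, params: dict, cfg: TrainingConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for k, gk in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * gk
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * gk * gk
            params[k] -= c.lr * (self.m[k] / bc1) / \
                (np.sqrt(self.v[k] / bc2) + c.eps)


def _batch_arrays(session: Session, slices, dtype=np.float32):
    """Padded observation, transition-reward and mask arrays for episodes."""
    obs = session.observations
    rew = session.rewards
    L = max(b - a for a, b in slices)
    B = len(slices)
    X = np.zeros((B, L, N_INPUTS), dtype=dtype)
    R = np.zeros((B, L), dtype=dtype)  # R[b, t] = reward on transition t -> t+1
    pair = np.zeros((B, L), dtype=bool)
    for i, (a, b) in enumerate(slices):
        n = b - a
        X[i, :n] = obs[a:b]
        R[i, :n - 1] = rew[a + 1:b]
        pair[i, :n - 1] = True
    return X, R, pair


def train_value_rnn(config: TrainingConfig, session: Session,
                    init: GruParams, freeze_recurrent: bool = False,
                    verbose: bool = False) -> RecurrentValueModel:
    """Train a Value RNN by semi-gradient TD(0) with BPTT over episodes.

    The session is split into fixed-length episodes; the hidden state is
    reset to zero at each episode start and episodes are the truncation
    unit for backpropagation. Each epoch is one pass over all episodes in a
    randomized batch order; the epoch mean loss is logged and training
    stops early after ``early_stop_patience`` consecutive epoch-loss
    increases. With ``freeze_recurrent=True`` (the Value-ESN mode) only the
    readout ``(w, w0)`` is updated.
    """
    ep_len = config.resolved_episode_len(session.config.task_id)
    slices = episode_slices(session, ep_len)
    rng = np.random.default_rng(config.seed)

    H = init.H
    a = 1.0 / np.sqrt(H)
    # training runs in single precision: ample for TD errors of this scale
    dt = np.float32
    params = {"W_i": init.W_i.astype(dt), "W_h": init.W_h.astype(dt),
              "b_i": init.b_i.astype(dt), "b_h": init.b_h.astype(dt),
              "w": rng.uniform(-a, a, size=H).astype(dt),
              "w0": rng.uniform(-a, a, size=1).astype(dt)}
    trained_keys = ["w", "w0"] if freeze_recurrent else list(params)
    opt = _Adam({k: params[k] for k in trained_keys}, config)

    # numpy forward (SIMD transcendentals) + jitted backward is fastest here
    fwd = _forward_batch
    bwd = _backward_batch_fast if _HAVE_NUMBA else _backward_batch
    gamma = config.gamma
    losses = []
    n_increases = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(slices))
        batch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [slices[j] for j in order[start:start + config.batch_size]]
            X, R, pair = _batch_arrays(session, batch)
            cell = GruParams(params["W_i"], params["W_h"],
                             params["b_i"], params["b_h"])
            Hs, cache = fwd(cell, X)
            V = Hs @ params["w"] + params["w0"]           # (B, L)
            delta = np.where(pair, R + gamma * np.roll(V, -1, axis=1) - V, 0.0)
            n_pairs = int(pair.sum())
            loss = float((delta ** 2).sum() / n_pairs)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"TD loss diverged (epoch {epoch}): check learning rate")
            batch_losses.append(loss)
            # semi-gradient: d loss / d V_t = -2 delta_t / n (target detached)
            dV = -2.0 * delta / n_pairs
            gw = np.tensordot(dV, Hs, axes=([0, 1], [0, 1]))
            gw0 = np.array([dV.sum()])
            grads = {"w": gw, "w0": gw0}
            if not freeze_recurrent:
                dH = dV[:, :, None] * params["w"][None, None, :]
                grads.update(bwd(cell, X, cache, dH))
            opt.step(params, grads)
        epoch_loss = float(np.mean(batch_losses))
        if verbose:
            print(f"epoch {epoch:3d}  loss {epoch_loss:.6f}")
        if losses and epoch_loss > losses[-1]:
            n_increases += 1
        else:
            n_increases = 0
        losses.append(epoch_loss)
        if n_increases >= config.early_stop_patience:
            break

    if freeze_recurrent:
        cell = init.copy()  # bit-identical frozen cell
    else:
        cell = GruParams(params["W_i"].astype(float), params["W_h"].astype(float),
                         params["b_i"].astype(float), params["b_h"].astype(float))
    readout = ValueWeights(w=params["w"].astype(float),
                           w0=float(params["w0"][0]), gamma=gamma)
    prov = "esn" if freeze_recurrent else "value_rnn"
    return RecurrentValueModel(cell=cell, readout=readout, provenance=prov,
                               train_log=losses, seed=config.seed)


# ---------------------------------------------------------------------------
# serialization: portable npz container with a JSON header

def save_model(model: RecurrentValueModel, path) -> None:
    header = json.dumps({"provenance": model.provenance, "seed": model.seed,
                         "gamma": model.readout.gamma,
                         "train_log": list(model.train_log)})
    np.savez(path, header=header, W_i=model.cell.W_i, W_h=model.cell.W_h,
             b_i=model.cell.b_i, b_h=model.cell.b_h,
             w=model.readout.w, w0=np.array([model.readout.w0]))


def load_model(path) -> RecurrentValueModel:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["header"]))
        cell = GruParams(f["W_i"], f["W_h"], f["b_i"], f["b_h"])
        readout = ValueWeights(w=f["w"], w0=float(f["w0"][0]),
                               gamma=meta["gamma"])
    return RecurrentValueModel(cell=cell, readout=readout,
                               provenance=meta["provenance"],
                               train_log=meta["train_log"], seed=meta["seed"])
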