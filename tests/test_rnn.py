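"""GRU cell, initializations, rollouts, and TD training."""

import numpy as np
import pytest

from beliefrl import dynamics, rnn
from beliefrl.rnn import (
    GruParams,
    TrainingConfig,
    gru_step,
    init_default,
    init_esn,
    load_model,
    rollout,
    save_model,
    train_value_rnn,
)
from beliefrl.tasks import make_config, sample_session


def reference_gru_step(params, z, o):
    """Independent scalar-loop transcription of the gated update."""
    H = params.H
    W_ir, W_iz, W_in = params.W_i[:H], params.W_i[H:2 * H], params.W_i[2 * H:]
    W_hr, W_hz, W_hn = params.W_h[:H], params.W_h[H:2 * H], params.W_h[2 * H:]
    b_ir, b_iz, b_in = params.b_i[:H], params.b_i[H:2 * H], params.b_i[2 * H:]
    b_hr, b_hz, b_hn = params.b_h[:H], params.b_h[H:2 * H], params.b_h[2 * H:]
    out = np.empty(H)
    for i in range(H):
        r = 1 / (1 + np.exp(-(W_ir[i] @ o + b_ir[i] + W_hr[i] @ z + b_hr[i])))
        u = 1 / (1 + np.exp(-(W_iz[i] @ o + b_iz[i] + W_hz[i] @ z + b_hz[i])))
        n = np.tanh(W_in[i] @ o + b_in[i] + r * (W_hn[i] @ z + b_hn[i]))
        out[i] = (1 - u) * n + u * z[i]
    return out


def zero_params(H):
    return GruParams(np.zeros((3 * H, 2)), np.zeros((3 * H, H)),
                     np.zeros(3 * H), np.zeros(3 * H))


class TestGruStep:
    def test_zero_parameters_halve_state(self):
        # u = 1/2 and n = 0, so z' = z/2
        z = np.array([0.8, -0.4, 0.2])
        out = gru_step(zero_params(3), z, np.zeros(2))
        np.testing.assert_allclose(out, z / 2)

    def test_saturated_update_gate_is_perfect_memory(self):
        p = zero_params(3)
        p.b_i[3:6] = 50.0  # update-gate bias -> u ~= 1
        z = np.array([0.3, -0.9, 0.5])
        out = gru_step(p, z, np.ones(2))
        np.testing.assert_allclose(out, z, atol=1e-12)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        p = init_default(7, seed=1)
        for _ in range(5):
            z = rng.standard_normal(7)
            o = rng.standard_normal(2)
            np.testing.assert_allclose(gru_step(p, z, o),
                                       reference_gru_step(p, z, o), atol=1e-6)

    def test_state_envelope(self):
        # each coordinate is a convex mix of z_prev and tanh output
        rng = np.random.default_rng(1)
        p = init_default(5, seed=2)
        z = rng.uniform(-2, 2, 5)
        out = gru_step(p, z, rng.standard_normal(2))
        assert np.all(out >= np.minimum(z, -1) - 1e-12)
        assert np.all(out <= np.maximum(z, 1) + 1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            gru_step(zero_params(2), np.array([np.nan, 0.0]), np.zeros(2))


class TestInitDefault:
    def test_bound_and_moments(self):
        p = init_default(4, seed=0)
        for a in (p.W_i, p.W_h, p.b_i, p.b_h):
            assert np.all(np.abs(a) < 0.5)  # 1/sqrt(4)
        draws = np.concatenate([init_default(50, seed=s).W_h.ravel()
                                for s in range(5)])
        a = 1 / np.sqrt(50)
        assert abs(draws.mean()) < 0.005
        assert draws.var() == pytest.approx(a ** 2 / 3, rel=0.05)

    def test_seed_reproducibility(self):
        a, b = init_default(6, seed=3), init_default(6, seed=3)
        np.testing.assert_array_equal(a.W_h, b.W_h)
        assert a.digest() == b.digest()

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            init_default(0, seed=0)


class TestInitEsn:
    def test_orthogonal_gain_blocks(self):
        gain = 1.3
        p = init_esn(20, gain, seed=0)
        for which in ("reset", "update", "candidate"):
            W = p.gate_block(which)
            np.testing.assert_allclose(W.T @ W, gain ** 2 * np.eye(20),
                                       atol=1e-8)
        assert np.all(p.b_i == 0) and np.all(p.b_h == 0)

    def test_input_weight_bound(self):
        H = 30
        p = init_esn(H, 1.0, seed=1)
        assert np.all(np.abs(p.W_i) <= np.sqrt(6 / (2 + H)))

    def test_gain_lengthens_odor_transient(self):
        """Higher gain means longer transient responses to an input."""
        cfg = dynamics.DynamicsConfig(max_steps=2000)
        durations = {}
        for gain in (0.9, 1.9):
            ts = []
            for s in range(8):
                p = init_esn(50, gain, seed=s)
                null_step = lambda z: gru_step(p, z, np.zeros(2))
                fps = dynamics.find_fixed_points(null_step, [np.zeros(50)], cfg)
                odor = lambda z: gru_step(p, z, np.array([1.0, 0.0]))
                ts.append(dynamics.memory_duration(null_step, odor,
                                                   fps.points[0], cfg))
            durations[gain] = np.median(ts)
        assert durations[1.9] > durations[0.9]

    def test_invalid_gain(self):
        with pytest.raises(ValueError):
            init_esn(5, -1.0, seed=0)


class TestRollout:
    def test_zero_parameter_decay(self):
        obs = np.zeros((60, 2))
        Z = rollout(zero_params(3), obs, z0=np.ones(3))
        assert np.all(np.abs(Z[-1]) < 1e-15)

    def test_determinism(self):
        p = init_default(8, seed=4)
        s = sample_session(make_config("starkweather1"), 20, seed=5)
        np.testing.assert_array_equal(rollout(p, s), rollout(p, s))

    def test_untrained_transient_response(self):
        """An untrained GRU responds transiently to an observation and
        relaxes back toward its resting state."""
        p = init_default(50, seed=6)
        null_step = lambda z: gru_step(p, z, np.zeros(2))
        fps = dynamics.find_fixed_points(null_step, [np.zeros(50)])
        z0 = fps.points[0]
        z = gru_step(p, z0, np.array([1.0, 0.0]))
        d0 = np.linalg.norm(z - z0)
        assert d0 > 1e-3  # perturbed by the input
        for _ in range(500):
            z = null_step(z)
        assert np.linalg.norm(z - z0) < d0 / 10  # decays back

    def test_episode_reset(self):
        p = init_default(4, seed=7)
        obs = np.random.default_rng(0).random((40, 2))
        Z = rollout(p, obs, episode_bounds=[(0, 20), (20, 40)])
        Z2 = rollout(p, obs[20:])
        np.testing.assert_allclose(Z[20:], Z2)


@pytest.fixture(scope="module")
def small_session():
    return sample_session(make_config("starkweather2"), 400, seed=8)


class TestTraining:
    def test_loss_decreases(self, small_session):
        init = init_default(16, seed=9)
        m = train_value_rnn(TrainingConfig(max_epochs=10, seed=9),
                            small_session, init)
        assert m.train_log[-1] < m.train_log[0]
        assert m.provenance == "value_rnn"

    def test_frozen_cell_unchanged(self, small_session):
        init = init_esn(16, 1.3, seed=10)
        digest = init.digest()
        m = train_value_rnn(TrainingConfig(max_epochs=3, seed=10),
                            small_session, init, freeze_recurrent=True)
        assert m.cell.digest() == digest
        assert m.provenance == "esn"

    def test_training_reproducible(self, small_session):
        init = init_default(8, seed=11)
        tc = TrainingConfig(max_epochs=3, seed=11)
        a = train_value_rnn(tc, small_session, init)
        b = train_value_rnn(tc, small_session, init)
        np.testing.assert_array_equal(a.cell.W_h, b.cell.W_h)
        np.testing.assert_array_equal(a.readout.w, b.readout.w)

    def test_semi_gradient_matches_finite_differences(self):
        """BPTT gradients agree with numerical differentiation of the
        detached-target squared TD error."""
        from beliefrl.rnn import _backward_batch, _forward_batch

        rng = np.random.default_rng(12)
        H, B, T = 4, 3, 6
        p = init_default(H, seed=13)
        X = rng.standard_normal((B, T, 2))
        w = rng.standard_normal(H)
        R = rng.standard_normal((B, T))
        pair = np.ones((B, T), dtype=bool)
        pair[:, -1] = False
        gamma, n = 0.9, pair.sum()

        Hs, cache = _forward_batch(p, X)
        V = Hs @ w
        delta = np.where(pair, R + gamma * np.roll(V, -1, 1) - V, 0.0)
        dV = -2.0 * delta / n
        g = _backward_batch(p, X, cache, dV[:, :, None] * w)

        eps = 1e-6
        for name in ("W_i", "W_h", "b_i", "b_h"):
            A = getattr(p, name)
            it = np.nditer(A, flags=["multi_index"])
            num = np.zeros_like(A)
            for _ in it:
                i = it.multi_index
                orig = A[i]
                A[i] = orig + eps
                Vp = _forward_batch(p, X)[0] @ w
                A[i] = orig - eps
                Vm = _forward_batch(p, X)[0] @ w
                A[i] = orig
                num[i] = (dV * (Vp - Vm) / (2 * eps)).sum()
            np.testing.assert_allclose(g[name], num, atol=1e-7 * max(1, np.abs(num).max() * 10))

    def test_save_load_roundtrip(self, small_session, tmp_path):
        init = init_default(8, seed=14)
        m = train_value_rnn(TrainingConfig(max_epochs=2, seed=14),
                            small_session, init)
        path = tmp_path / "model.npz"
        save_model(m, path)
        m2 = load_model(path)
        np.testing.assert_array_equal(m.cell.W_h, m2.cell.W_h)
        assert m2.readout.w0 == m.readout.w0
        assert m2.provenance == m.provenance
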