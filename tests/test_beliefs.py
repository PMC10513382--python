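"""Belief computation: POMDP construction, Bayes filtering, fixed points."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beliefrl import value
from beliefrl.beliefs import (
    OBS_CLASSES,
    POMDPSpec,
    belief_fixed_points,
    block_posterior_from_reward,
    build_babayan_block_pomdp,
    build_starkweather_pomdp,
    classify_observation,
    compute_babayan_beliefs,
    compute_beliefs,
    update_belief,
)
from beliefrl.tasks import make_config, sample_session


# ---------------------------------------------------------------------------
# independent oracle: posterior by exhaustive enumeration of state paths

def enumeration_posterior(spec, obs_seq):
    """P(s_T | o_1..o_T) by summing over every state path explicitly."""
    K = spec.K
    paths = [(k, p) for k, p in enumerate(spec.b0) if p > 0]
    for o in obs_seq:
        new = []
        for k_prev, p in paths:
            for k in range(K):
                w = spec.T_mat[k, k_prev] * spec.O[o][k, k_prev]
                if w > 0:
                    new.append((k, p * w))
        paths = new
    post = np.zeros(K)
    for k, p in paths:
        post[k] += p
    total = post.sum()
    return post / total if total > 0 else None


def random_pomdp(rng, K):
    """A random valid spec: column-stochastic T with each transition
    assigned exactly one emission class."""
    T = rng.random((K, K)) * (rng.random((K, K)) < 0.7)
    T[rng.integers(K), np.arange(K)] += 0.5  # ensure no empty column
    T /= T.sum(axis=0, keepdims=True)
    O = {o: np.zeros((K, K)) for o in OBS_CLASSES}
    cls = rng.integers(0, 3, size=(K, K))
    for i, o in enumerate(OBS_CLASSES):
        O[o][(cls == i) & (T > 0)] = 1.0
    b0 = rng.dirichlet(np.ones(K))
    return POMDPSpec(K=K, T_mat=T, O=O, state_labels=["s"] * K,
                     hazard=np.zeros(1), b0=b0)


class TestConstruction:
    def test_starkweather_state_count(self):
        for task in (1, 2):
            assert build_starkweather_pomdp(task).K == 25

    def test_babayan_state_counts(self):
        spec = build_babayan_block_pomdp()
        assert spec.K == 22
        sess = sample_session(make_config("babayan"), 20, seed=0)
        traj = compute_babayan_beliefs(spec, sess)
        assert traj.B.shape[1] == 44

    def test_columns_stochastic(self):
        for spec in (build_starkweather_pomdp(1), build_starkweather_pomdp(2),
                     build_babayan_block_pomdp()):
            np.testing.assert_allclose(spec.T_mat.sum(axis=0), 1.0)

    def test_hazards(self):
        s = build_starkweather_pomdp(2)
        assert s.hazard[13] == 1.0  # last possible reward time
        b = build_babayan_block_pomdp()
        np.testing.assert_allclose(b.hazard[8:], [1 / 3, 1 / 2, 1.0])

    def test_emission_support_matches_transitions(self):
        spec = build_starkweather_pomdp(2)
        spec.validate()
        total = sum(spec.O.values())
        assert np.array_equal(total > 0, spec.T_mat > 0)

    def test_task1_is_zero_omission_task2(self):
        t1 = build_starkweather_pomdp(1)
        t2 = build_starkweather_pomdp(2)
        assert t1.T_mat[14, 24] == 0.0
        assert t2.T_mat[14, 24] == pytest.approx(1 / 8 * 0.1)
        assert t2.T_mat[0, 24] == pytest.approx(1 / 8 * 0.9)


class TestUpdateBelief:
    def test_iti_terminal_is_null_fixed_point(self):
        spec = build_starkweather_pomdp(2)
        b, n = update_belief(spec, spec.b0, "null")
        np.testing.assert_allclose(b, spec.b0, atol=1e-14)

    def test_toy_chain_matches_enumeration(self):
        rng = np.random.default_rng(0)
        spec = random_pomdp(rng, 3)
        obs = ["null", "odor"]
        b = spec.b0
        for o in obs:
            b, _ = update_belief(spec, b, o)
        expected = enumeration_posterior(spec, obs)
        assert expected is not None
        np.testing.assert_allclose(b, expected, atol=1e-10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), K=st.integers(3, 5),
           obs=st.lists(st.sampled_from(OBS_CLASSES), min_size=1, max_size=8))
    def test_filter_equals_path_enumeration(self, seed, K, obs):
        """Iterated one-step updates equal the exhaustive path-sum posterior."""
        rng = np.random.default_rng(seed)
        spec = random_pomdp(rng, K)
        expected = enumeration_posterior(spec, obs)
        b = spec.b0
        underflowed = False
        for o in obs:
            b, n = update_belief(spec, b, o)
            underflowed = underflowed or n < 1e-12
        if expected is None or underflowed:
            return  # observation sequence impossible under the model
        np.testing.assert_allclose(b, expected, atol=1e-10)

    def test_simplex_invariant(self):
        spec = build_starkweather_pomdp(2)
        sess = sample_session(make_config("starkweather2"), 300, seed=1)
        traj = compute_beliefs(spec, sess)
        np.testing.assert_allclose(traj.B.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(traj.B >= 0)

    def test_classify(self):
        assert classify_observation(1.0, 0.0) == "odor"
        assert classify_observation(0.0, 2.0) == "reward"
        assert classify_observation(0.0, 0.0) == "null"
        with pytest.raises(ValueError):
            classify_observation(1.0, 1.0)


class TestComputeBeliefs:
    def test_argmax_tracks_macro_state_task1(self):
        """In the fully observable task the belief argmax follows the true
        ISI/ITI macro-state exactly (after the first reward anchors it)."""
        cfg = make_config("starkweather1")
        sess = sample_session(cfg, 200, seed=2)
        spec = build_starkweather_pomdp(1)
        traj = compute_beliefs(spec, sess)
        start = sess.reward_times[0] + 1
        is_isi_true = sess.states[start:] < 14
        is_isi_belief = np.argmax(traj.B[start:], axis=1) < 14
        np.testing.assert_array_equal(is_isi_belief, is_isi_true)

    def test_deterministic_toy_one_hot(self):
        # degenerate ISI and instant-cue limit make every state certain
        cfg = make_config("starkweather1", isi_support=(6,), p_iti=0.999999)
        spec = build_starkweather_pomdp(config=cfg)
        sess = sample_session(cfg, 10, seed=3)
        traj = compute_beliefs(spec, sess)
        after = sess.reward_times[0] + 1
        assert np.all(traj.B[after:].max(axis=1) > 1 - 1e-4)


class TestBabayanBeliefs:
    def test_likelihood_dominance_and_crossing(self):
        assert block_posterior_from_reward(1.0) > 1 - 1e-10
        assert block_posterior_from_reward(10.0) < 1e-10
        assert block_posterior_from_reward(5.5) == pytest.approx(0.5)

    def test_block_marginal(self):
        spec = build_babayan_block_pomdp()
        sess = sample_session(make_config("babayan"), 100, seed=4)
        traj = compute_babayan_beliefs(spec, sess)
        np.testing.assert_allclose(traj.B.sum(axis=1), 1.0, atol=1e-10)
        # marginal over the two block copies is (p, 1-p): both nonnegative
        p = traj.B[:, :22].sum(axis=1)
        assert np.all((p >= -1e-12) & (p <= 1 + 1e-12))

    def test_block2_reward_pins_posterior(self):
        spec = build_babayan_block_pomdp()
        sess = sample_session(make_config("babayan"), 50, seed=5)
        traj = compute_babayan_beliefs(spec, sess)
        p1 = traj.B[:, :22].sum(axis=1)
        for b in range(sess.trial_blocks.max() + 1):
            trials = np.flatnonzero(sess.trial_blocks == b)
            if sess.trial_rewards[trials[0]] != 10.0:
                continue
            first_rt = sess.reward_times[trials[0]]
            last = sess.trial_slices()[trials[-1]][1]
            assert np.all(p1[first_rt:last] < 1e-6)


class TestFixedPoints:
    def test_task2_unique_fixed_point(self):
        spec = build_starkweather_pomdp(2)
        fps = belief_fixed_points(spec)
        assert len(fps) == 1
        np.testing.assert_allclose(fps.points[0], spec.b0, atol=1e-3)

    def test_task1_unique_with_reset_rule(self):
        fps = belief_fixed_points(build_starkweather_pomdp(1))
        assert len(fps) == 1

    def test_fixed_points_on_simplex(self):
        fps = belief_fixed_points(build_starkweather_pomdp(2))
        for p in fps.points:
            assert p.sum() == pytest.approx(1.0, abs=1e-8)
            assert np.all(p >= -1e-12)


class TestValueLinearity:
    def test_lstd_on_beliefs_zeroes_mean_td_error(self, stark1_bundle):
        """The value function is linear in beliefs, so LSTD on beliefs
        leaves no systematic TD error."""
        b = stark1_bundle
        delta = value.td_errors(b.belief_values_eval,
                                value.transition_rewards(b.eval), b.gamma)
        d = delta[~np.isnan(delta)]
        assert abs(d.mean()) < 3 * d.std() / np.sqrt(d.size)
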