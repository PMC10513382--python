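"""Shared fixtures: analysis sessions with beliefs, and trained networks.

Trained-network fixtures use a scaled-down protocol (fewer replicates,
shorter sessions and epoch caps than the full study) so the whole suite
runs at desk scale; the training code path is exactly the full one.
"""

import numpy as np
import pytest

from beliefrl import rnn, value
from beliefrl.experiment import derive_seed, task_beliefs
from beliefrl.tasks import make_config, sample_session


class AnalysisBundle:
    """Fit/eval session pair with beliefs and the belief-model RPE reference."""

    def __init__(self, task_id, n_trials=1000, base_seed=11, gamma=0.93):
        self.task_id = task_id
        self.gamma = gamma
        cfg = make_config(task_id)
        self.fit = sample_session(cfg, n_trials, derive_seed(base_seed, task_id, "fit"))
        self.eval = sample_session(cfg, n_trials, derive_seed(base_seed, task_id, "eval"))
        self.spec, self.traj_fit = task_beliefs(self.fit)
        _, self.traj_eval = task_beliefs(self.eval)
        w = value.lstd_weights(self.traj_fit.B,
                               value.transition_rewards(self.fit), gamma)
        self.belief_values_eval = value.value_estimate(self.traj_eval.B, w)
        self.belief_rpe = value.rpe_trace(self.eval, self.belief_values_eval, gamma)


@pytest.fixture(scope="session")
def stark1_bundle():
    return AnalysisBundle("starkweather1")


@pytest.fixture(scope="session")
def stark2_bundle():
    return AnalysisBundle("starkweather2")


@pytest.fixture(scope="session")
def babayan_bundle():
    return AnalysisBundle("babayan", n_trials=500)


# scaled-down training protocol shared by every trained-network fixture
N_TRAIN_TRIALS = 8000
TRAIN_SEEDS = (0, 1)
TRAIN_CONFIG = dict(max_epochs=90, early_stop_patience=8)


def _train(task_id, seed, H=50):
    cfg = make_config(task_id)
    sess = sample_session(cfg, N_TRAIN_TRIALS,
                          derive_seed(seed, task_id, "train_session"))
    init = rnn.init_default(H, derive_seed(seed, task_id, "init"))
    tc = rnn.TrainingConfig(seed=seed, **TRAIN_CONFIG)
    model = rnn.train_value_rnn(tc, sess, init)
    untrained = rnn.RecurrentValueModel(
        cell=init, readout=model.readout, provenance="untrained", seed=seed)
    return model, untrained


@pytest.fixture(scope="session")
def trained_stark1():
    """(trained, untrained) pairs for Starkweather Task 1, H = 50."""
    return [_train("starkweather1", s) for s in TRAIN_SEEDS]


@pytest.fixture(scope="session")
def trained_stark2():
    """(trained, untrained) pairs for Starkweather Task 2, H = 50."""
    return [_train("starkweather2", s) for s in TRAIN_SEEDS]
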