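"""Quantifying how belief-like a learned representation is.

Three statistical probes, each fit on one session and evaluated on an
independent held-out session:

* **Belief regression**: ordinary least squares from the (noisy)
  representation to the belief vectors; reported as the *pooled* variance
  explained, ``R^2 = 1 - Var(B - Z W) / Var(B)`` with
  ``Var(X) = mean_t ||x_t - x_bar||^2`` (one scalar across all belief
  dimensions, negative values possible on held-out data).
* **State decoding**: multinomial logistic regression from the standardized
  representation to the true microstate, scored by the mean held-out
  log-likelihood of the true state. Using the beliefs themselves as the
  decoded probabilities is a ceiling on this score.
* **PCA projection** of activity for visualization.

Because RNN activity is a deterministic function of its inputs, Gaussian
noise is added to every unit before regression/decoding: unit ``i`` gets sd
``g * sigma_i`` (its own sample sd scaled by the gain ``g``), so every unit
has the same signal-to-noise ratio, SNR = -20 log10(g) dB (26 dB at the
default g = 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

__all__ = [
    "NoiseConfig",
    "DecoderModel",
    "snr_db",
    "add_representation_noise",
    "belief_r2",
    "fit_state_decoder",
    "decoder_loglik",
    "belief_loglik",
    "pca_project",
]

LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class NoiseConfig:
    g: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("noise gain must be >= 0")


def snr_db(g: float) -> float:
    """Per-unit signal-to-noise ratio in dB for noise gain ``g``."""
    return float(-20.0 * np.log10(g))


def add_representation_noise(Z: np.ndarray, config: NoiseConfig) -> np.ndarray:
    """Add zero-mean Gaussian noise with per-unit sd ``g * sigma_i``.

    Zero-variance units receive no noise (with a warning); ``g = 0`` is the
    identity.
    """
    Z = np.asarray(Z, dtype=float)
    if config.g == 0:
        return Z.copy()
    sd = Z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        warnings.warn("zero-variance unit(s): no noise added to them")
    rng = np.random.default_rng(config.seed)
    return Z + rng.standard_normal(Z.shape) * (config.g * sd)


def _total_variance(X: np.ndarray) -> float:
    """mean_t ||x_t - x_bar||^2 (pooled across columns)."""
    return float(np.mean(np.sum((X - X.mean(axis=0)) ** 2, axis=1)))


def belief_r2(Z_fit: np.ndarray, B_fit: np.ndarray,
              Z_eval: np.ndarray, B_eval: np.ndarray) -> float:
    """Held-out pooled variance of beliefs explained by an affine readout.

    The regression weights are the least-squares solution on the fit split
    (with a constant-1 column for the intercept); R^2 is evaluated on the
    eval split and can be negative for bad fits. Rank-deficient designs are
    handled by the minimum-norm solution.
    """
    def aug(Z):
        return np.column_stack([np.asarray(Z, dtype=float),
                                np.ones(len(Z))])
    Zf, Ze = aug(Z_fit), aug(Z_eval)
    W, _, rank, _ = np.linalg.lstsq(Zf, np.asarray(B_fit, dtype=float),
                                    rcond=None)
    if rank < Zf.shape[1]:
        warnings.warn("rank-deficient representation; using pseudoinverse")
    resid = np.asarray(B_eval, dtype=float) - Ze @ W
    return float(1.0 - _total_variance(resid) / _total_variance(B_eval))


@dataclass
class DecoderModel:
    """Multinomial logistic state decoder with its standardization stats."""

    mean: np.ndarray
    sd: np.ndarray
    clf: LogisticRegression
    n_states: int

    def standardize(self, Z: np.ndarray) -> np.ndarray:
        return (np.asarray(Z, dtype=float) - self.mean) / self.sd

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        """(T, n_states) probabilities over the full state set; states never
        seen during fitting get probability 0."""
        p_seen = self.clf.predict_proba(self.standardize(Z))
        out = np.zeros((len(p_seen), self.n_states))
        out[:, self.clf.classes_] = p_seen
        return out


def fit_state_decoder(Z_fit: np.ndarray, states_fit: np.ndarray,
                      n_states: int | None = None, C: float = 1.0,
                      max_iter: int = 10_000) -> DecoderModel:
    """Fit a multinomial logistic decoder of the microstate.

    Features are standardized per dimension using fit-split statistics (no
    leakage); the quadratic penalty (inverse strength ``C``) excludes the
    intercept. States absent from the fit split are assigned zero
    probability, with a warning.
    """
    states_fit = np.asarray(states_fit, dtype=int)
    if n_states is None:
        n_states = int(states_fit.max()) + 1
    Z_fit = np.asarray(Z_fit, dtype=float)
    mean = Z_fit.mean(axis=0)
    sd = Z_fit.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    clf = LogisticRegression(C=C, max_iter=max_iter)
    clf.fit((Z_fit - mean) / sd, states_fit)
    if len(clf.classes_) < n_states:
        warnings.warn("some states unseen in the fit split; "
                      "they get zero decoded probability")
    return DecoderModel(mean=mean, sd=sd, clf=clf, n_states=n_states)


def decoder_loglik(model: DecoderModel, Z_eval: np.ndarray,
                   states_eval: np.ndarray,
                   sample_mask: np.ndarray | None = None) -> float:
    """Mean held-out log-likelihood of the true states under the decoder.

    ``sample_mask`` restricts the average to a subset of steps (used to
    exclude each block's first trial in the Babayan task); excluded steps do
    not count in the denominator. Zero probabilities are floored.
    """
    pi = model.predict_proba(Z_eval)
    return _mean_loglik(pi, states_eval, sample_mask)


def belief_loglik(B_eval: np.ndarray, states_eval: np.ndarray,
                  sample_mask: np.ndarray | None = None) -> float:
    """Mean log-likelihood when the beliefs themselves are the decoded
    probabilities (no decoder is trained); a ceiling for decoders fit on
    any representation of the same observations."""
    return _mean_loglik(np.asarray(B_eval, dtype=float),
                        np.asarray(states_eval), sample_mask)


def _mean_loglik(pi: np.ndarray, states: np.ndarray,
                 sample_mask: np.ndarray | None) -> float:
    states = np.asarray(states, dtype=int)
    p = pi[np.arange(len(states)), states]
    if sample_mask is not None:
        p = p[np.asarray(sample_mask, dtype=bool)]
    return float(np.mean(np.log(np.maximum(p, LOG_FLOOR))))


def pca_project(Z: np.ndarray, n_components: int = 2):
    """Centered PCA projection; returns ``(projection, explained_fractions)``."""
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(np.asarray(Z, dtype=float))
    return proj, pca.explained_variance_ratio_
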