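"""Dynamical-systems characterization of recurrent maps.

Works on any deterministic state-update function ``z -> f(z, null)`` —
a GRU driven by the null observation, or the belief recursion itself.

* **Fixed points**: iterate the null-input map from data-derived seeds
  (states just after an odor or reward) until the consecutive-step squared
  distance falls below ``fp_tol``; merge converged points within
  ``merge_dist`` of each other (single-linkage, order-independent).
* **Observation memory**: starting *at* a fixed point, apply one odor (or
  reward) observation at ``t = 1``, then nulls; the memory is the first
  ``t`` at which the squared distance back to the fixed point drops below
  ``return_tol``. A system the probe never perturbs has memory 1. Trained
  value networks show odor memories tied to the latest possible reward time
  and reward memories tied to the minimum ITI, so odor memory exceeds
  reward memory — a signature that reservoir-style networks lack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DynamicsConfig",
    "FixedPointSet",
    "find_fixed_points",
    "memory_duration",
    "memory_difference",
    "NOT_RETURNED",
]

#: sentinel for probes that never return to the fixed point within max_steps
NOT_RETURNED = -1


@dataclass(frozen=True)
class DynamicsConfig:
    fp_tol: float = 1e-5       # squared consecutive-step convergence threshold
    merge_dist: float = 1e-3   # (plain) distance below which points merge
    return_tol: float = 1e-3   # squared distance-to-fixed-point threshold
    n_seeds: int = 20
    max_steps: int = 1000
    polish_steps: int = 2000   # extra iterations to pin down converged points

    def __post_init__(self):
        if min(self.fp_tol, self.merge_dist, self.return_tol) <= 0 \
                or self.n_seeds < 1 or self.max_steps < 1:
            raise ValueError("all dynamics thresholds must be positive")


@dataclass
class FixedPointSet:
    """Merged null-input fixed points with convergence diagnostics."""

    points: list               # representative state per merged cluster
    residuals: np.ndarray      # ||f(z) - z||^2 at each representative
    basin_seed_counts: np.ndarray  # seeds that converged into each cluster
    n_failed: int = 0          # seeds that did not converge within max_steps

    def __len__(self) -> int:
        return len(self.points)


def _merge_clusters(points: list, config: DynamicsConfig):
    """Single-linkage clustering at merge_dist; order-independent."""
    n = len(points)
    parent = list(range(n))

    def root(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) < config.merge_dist:
                parent[root(i)] = root(j)
    clusters = {}
    for i in range(n):
        clusters.setdefault(root(i), []).append(i)
    return list(clusters.values())


def find_fixed_points(step_fn, seeds, config: DynamicsConfig | None = None
                      ) -> FixedPointSet:
    """Locate null-input fixed points by iterating from each seed state.

    ``step_fn`` maps a state to its successor under null input. Each seed is
    iterated until the squared step ``||z_t - z_{t-1}||^2 < fp_tol`` or
    ``max_steps``; converged endpoints are merged within ``merge_dist``. The
    representative of each cluster is its member with the smallest residual
    ``||f(z) - z||^2``. Non-convergence is flagged, not fatal.

    After the stopping criterion fires, the point is *polished* by up to
    ``polish_steps`` further iterations (while the step keeps shrinking).
    With slowly contracting maps the raw criterion can stop well away from
    the attractor, scattering near-duplicate candidates and corrupting
    downstream distance-to-fixed-point measurements; polishing pins each
    candidate to the attractor it was already converging to.
    """
    if config is None:
        config = DynamicsConfig()
    converged = []
    n_failed = 0
    for z in list(seeds)[: config.n_seeds]:
        z = np.asarray(z, dtype=float)
        ok = False
        for _ in range(config.max_steps):
            z_new = np.asarray(step_fn(z), dtype=float)
            if float(np.sum((z_new - z) ** 2)) < config.fp_tol:
                z = z_new
                ok = True
                break
            z = z_new
        if ok:
            step = np.inf
            for _ in range(config.polish_steps):
                z_new = np.asarray(step_fn(z), dtype=float)
                step_new = float(np.sum((z_new - z) ** 2))
                z = z_new
                if step_new >= step or step_new == 0.0:
                    break
                step = step_new
            converged.append(z)
        else:
            n_failed += 1
    if not converged:
        return FixedPointSet(points=[], residuals=np.empty(0),
                             basin_seed_counts=np.empty(0, dtype=int),
                             n_failed=n_failed)
    clusters = _merge_clusters(converged, config)
    points, residuals, counts = [], [], []
    for members in clusters:
        cand = [converged[i] for i in members]
        res = [float(np.sum((np.asarray(step_fn(z)) - z) ** 2)) for z in cand]
        best = int(np.argmin(res))
        points.append(cand[best])
        residuals.append(res[best])
        counts.append(len(members))
    order = np.argsort([-c for c in counts])
    return FixedPointSet(points=[points[i] for i in order],
                         residuals=np.asarray(residuals)[order],
                         basin_seed_counts=np.asarray(counts, dtype=int)[order],
                         n_failed=n_failed)


def memory_duration(step_fn, probe_fn, fixed_point: np.ndarray,
                    config: DynamicsConfig | None = None) -> int:
    """Steps for the state to return to ``fixed_point`` after one probe.

    ``probe_fn`` applies the probed observation (odor or reward) to a state;
    it acts at ``t = 1``, nulls follow. Returns the first ``t`` with
    ``||z_t - z_0||^2 < return_tol``, or :data:`NOT_RETURNED` if the cap is
    reached.
    """
    if config is None:
        config = DynamicsConfig()
    z0 = np.asarray(fixed_point, dtype=float)
    z = np.asarray(probe_fn(z0), dtype=float)
    for t in range(1, config.max_steps + 1):
        if float(np.sum((z - z0) ** 2)) < config.return_tol:
            return t
        z = np.asarray(step_fn(z), dtype=float)
    return NOT_RETURNED


def memory_difference(step_fn, odor_probe_fn, reward_probe_fn,
                      fixed_point: np.ndarray,
                      config: DynamicsConfig | None = None) -> dict:
    """Odor memory, reward memory, and their signed difference (in steps).

    The difference is NaN if either probe never returns within the cap.
    """
    om = memory_duration(step_fn, odor_probe_fn, fixed_point, config)
    rm = memory_duration(step_fn, reward_probe_fn, fixed_point, config)
    diff = float(om - rm) if (om != NOT_RETURNED and rm != NOT_RETURNED) \
        else float("nan")
    return {"odor_memory": om, "reward_memory": rm, "memory_diff": diff}
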