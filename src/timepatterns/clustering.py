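"""Spherical K-means on unit profiles with subsampled K-means++ seeding.

Spherical K-means maximises the total cosine similarity between each profile
and its cluster centroid: assignment picks the centroid of maximal dot
product, and the centroid update is the renormalized cluster mean.  Because
all points live on the unit sphere, the cosine objective and the Euclidean
within-cluster sum of squares are two views of the same quantity:
``wcss = 2 * (n - objective)`` when centroids are unit-norm.

Seeding follows K-means++ D-squared sampling with cosine distance
``d(x, c) = 1 - x . c``, restricted to a uniformly drawn subsample of the
profiles (10% by default) to keep seeding cheap on large gene sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import UnitProfileMatrix

__all__ = ["ClusterResult", "seed_centroids_pp", "spherical_kmeans", "total_wcss"]


@dataclass
class ClusterResult:
    """Result of one spherical K-means fit (best restart)."""

    assignments: np.ndarray          # per-gene cluster index in [0, n_clusters)
    centroids: np.ndarray            # (n_clusters, C*T), unit-norm rows
    objective: float                 # sum over genes of cos(gene, centroid)
    inertia: float                   # total within-cluster sum of squares
    n_iter: int
    seed: int
    objective_history: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_clusters)


def _as_array(profiles) -> np.ndarray:
    if isinstance(profiles, UnitProfileMatrix):
        return profiles.vectors
    return np.asarray(profiles, dtype=float)


def seed_centroids_pp(
    profiles,
    k: int,
    subsample_fraction: float = 0.1,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """K-means++ D^2 seeding over a uniform subsample of the profiles.

    The first centroid is drawn uniformly from the subsample; each further
    centroid is drawn with probability proportional to the squared cosine
    distance to the nearest centroid chosen so far.  When the subsample is
    smaller than ``k`` all profiles are used instead.
    """
    x = _as_array(profiles)
    n = x.shape[0]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of profiles ({n})")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    m = math.ceil(subsample_fraction * n)
    if m < k:
        m = n
    idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
    pool = x[idx]

    chosen = [int(rng.integers(m))]
    dist = 1.0 - pool @ pool[chosen[0]]
    np.maximum(dist, 0.0, out=dist)
    for _ in range(1, k):
        w = dist**2
        total = w.sum()
        if total <= 0:
            # all remaining points coincide with a centroid; fall back to uniform
            candidates = np.setdiff1d(np.arange(m), np.array(chosen))
            nxt = int(rng.choice(candidates)) if candidates.size else int(rng.integers(m))
        else:
            nxt = int(rng.choice(m, p=w / total))
        chosen.append(nxt)
        np.minimum(dist, np.maximum(1.0 - pool @ pool[nxt], 0.0), out=dist)
    return pool[np.array(chosen)].copy()


def _normalize_rows(a: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(a, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return a / norms


def _lloyd(x: np.ndarray, k: int, centroids: np.ndarray, assignments: np.ndarray,
           max_iter: int, history: list[float]) -> tuple[np.ndarray, int]:
    """Batch assignment/update iterations until assignments stabilise."""
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        sims = x @ centroids.T
        new_assignments = np.argmax(sims, axis=1)  # ties break toward lowest index
        history.append(float(np.take_along_axis(sims, new_assignments[:, None], 1).sum()))
        if np.array_equal(new_assignments, assignments):
            break
        assignments = new_assignments
        for c in range(k):
            members = x[assignments == c]
            if len(members):
                s = members.sum(axis=0)
                norm = np.linalg.norm(s)
                if norm > 0:
                    centroids[c] = s / norm
            # empty clusters keep their previous centroid; dropped at the end
    return assignments, n_iter


def _first_variation(x: np.ndarray, k: int, assignments: np.ndarray) -> bool:
    """One greedy sweep of single-point moves on the exact objective.

    A fixed cluster's best objective contribution is the norm of its vector
    sum, so moving point i from cluster a to b changes the objective by
    (|s_a - x_i| + |s_b + x_i|) - (|s_a| + |s_b|).  Batch iterations stop at
    assignment-stable configurations that such moves can still improve; this
    local-search refinement is the standard escape for spherical K-means.
    """
    sums = np.zeros((k, x.shape[1]))
    np.add.at(sums, assignments, x)
    norms = np.linalg.norm(sums, axis=1)
    improved = False
    for i in range(x.shape[0]):
        a = assignments[i]
        out_norm = np.linalg.norm(sums[a] - x[i])
        gains = np.linalg.norm(sums + x[i], axis=1) - norms + (out_norm - norms[a])
        gains[a] = 0.0
        b = int(np.argmax(gains))
        if gains[b] > 1e-10:
            assignments[i] = b
            sums[a] -= x[i]
            sums[b] += x[i]
            norms[a] = np.linalg.norm(sums[a])
            norms[b] = np.linalg.norm(sums[b])
            improved = True
    return improved


def _single_run(x: np.ndarray, k: int, rng: np.random.Generator,
                max_iter: int, subsample_fraction: float):
    centroids = seed_centroids_pp(x, k, subsample_fraction, rng)
    assignments = np.full(x.shape[0], -1, dtype=int)
    history: list[float] = []
    n_iter = 0
    while n_iter < max_iter:
        assignments, used = _lloyd(x, k, centroids, assignments, max_iter - n_iter, history)
        n_iter += used
        if not _first_variation(x, k, assignments):
            break
        for c in range(k):
            members = x[assignments == c]
            if len(members):
                s = members.sum(axis=0)
                norm = np.linalg.norm(s)
                if norm > 0:
                    centroids[c] = s / norm
    sims = x @ centroids.T
    objective = float(np.take_along_axis(sims, assignments[:, None], 1).sum())
    if history and objective > history[-1]:
        history.append(objective)
    return assignments, centroids, objective, n_iter, history


def spherical_kmeans(
    profiles,
    k: int,
    rng_seed: int = 0,
    max_iter: int = 300,
    n_restarts: int = 5,
    subsample_fraction: float = 0.1,
) -> ClusterResult:
    """Fit spherical K-means, keeping the best of ``n_restarts`` seeded restarts.

    Deterministic given ``rng_seed``.  Clusters that end empty are dropped and
    the remaining clusters are renumbered in order, so the returned number of
    clusters can be smaller than ``k``.
    """
    x = _as_array(profiles)
    n = x.shape[0]
    if n == 0:
        raise ValueError("no profiles to cluster")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of profiles ({n})")

    root = np.random.SeedSequence(rng_seed)
    best = None
    for child in root.spawn(n_restarts):
        rng = np.random.default_rng(child)
        run = _single_run(x, k, rng, max_iter, subsample_fraction)
        if best is None or run[2] > best[2]:
            best = run
    assignments, centroids, objective, n_iter, history = best

    occupied = np.unique(assignments)
    remap = {old: new for new, old in enumerate(occupied)}
    assignments = np.array([remap[a] for a in assignments], dtype=int)
    centroids = centroids[occupied]

    result = ClusterResult(
        assignments=assignments,
        centroids=centroids,
        objective=objective,
        inertia=0.0,
        n_iter=n_iter,
        seed=rng_seed,
        objective_history=history,
    )
    result.inertia = total_wcss(result, x)
    return result


def total_wcss(result: ClusterResult, profiles) -> float:
    """Total within-cluster sum of squared Euclidean distances to assigned centroids."""
    x = _as_array(profiles)
    diffs = x - result.centroids[result.assignments]
    return float(np.einsum("ij,ij->", diffs, diffs))
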