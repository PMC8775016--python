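"""Elbow-method recommendation of the cluster count K.

Clustering is repeated over a grid of K values from 2 to ``kmax`` in steps of
``kmax / 10``, and the within-cluster sum of squares (WCSS) is averaged over
several seeded runs per K to smooth out the instability that random centroid
initialisation causes.  The recommended K is the grid point with the largest
perpendicular distance to the chord joining the first and last points of the
(normalized) K-vs-WCSS curve — the standard geometric reading of the elbow.
When that distance profile is nearly flat the curve has no clear elbow and
the result is flagged accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import spherical_kmeans, total_wcss

__all__ = ["KTestResult", "build_k_grid", "run_k_test"]

# Minimum normalized chord distance below which we consider the curve elbow-free.
FLAT_ELBOW_THRESHOLD = 0.05


@dataclass
class KTestResult:
    k_grid: list[int]
    mean_wcss: list[float]
    repeats: int
    recommended_k: int
    rng_seed: int
    elbow_strength: float = 0.0       # max normalized chord distance, in [0, ~0.5]
    no_clear_elbow: bool = False

    def as_rows(self):
        return list(zip(self.k_grid, self.mean_wcss))


def build_k_grid(kmax: int) -> list[int]:
    """Grid {2} U {round(i * kmax / 10) : i = 1..10}, deduplicated and sorted."""
    if kmax < 20:
        raise ValueError(f"kmax must be >= 20 (got {kmax}); smaller values degenerate the grid")
    grid = {2} | {round(i * kmax / 10) for i in range(1, 11)}
    return sorted(grid)


def _knee_point(ks: np.ndarray, wcss: np.ndarray) -> tuple[int, float]:
    """Index of max perpendicular distance to the first-to-last chord on normalized axes."""
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    span = wcss[0] - wcss[-1]
    if span == 0:
        return 0, 0.0
    y = (wcss - wcss[-1]) / span
    # chord runs (0, 1) -> (1, 0); distance = |x + y - 1| / sqrt(2)
    dist = np.abs(x + y - 1.0) / np.sqrt(2.0)
    i = int(np.argmax(dist))
    return i, float(dist[i])


def run_k_test(
    profiles,
    kmax: int,
    repeats: int = 5,
    rng_seed: int = 0,
    max_iter: int = 100,
    subsample_fraction: float = 0.1,
) -> KTestResult:
    """Average WCSS over ``repeats`` clustering runs per grid K and locate the elbow."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    grid = build_k_grid(kmax)
    n = profiles.vectors.shape[0] if hasattr(profiles, "vectors") else np.asarray(profiles).shape[0]
    if kmax >= n:
        raise ValueError(f"kmax={kmax} must be smaller than the number of genes ({n})")

    root = np.random.SeedSequence(rng_seed)
    run_seeds = root.generate_state(len(grid) * repeats) % (2**31)
    mean_wcss: list[float] = []
    for gi, k in enumerate(grid):
        wcss_vals = []
        for r in range(repeats):
            seed = int(run_seeds[gi * repeats + r])
            result = spherical_kmeans(
                profiles, k, rng_seed=seed, max_iter=max_iter,
                n_restarts=1, subsample_fraction=subsample_fraction,
            )
            wcss_vals.append(result.inertia)
        value = float(np.mean(wcss_vals))
        if not np.isfinite(value):
            raise RuntimeError(f"non-finite mean WCSS at K={k}")
        mean_wcss.append(value)

    idx, strength = _knee_point(np.array(grid, dtype=float), np.array(mean_wcss))
    return KTestResult(
        k_grid=grid,
        mean_wcss=mean_wcss,
        repeats=repeats,
        recommended_k=grid[idx],
        rng_seed=rng_seed,
        elbow_strength=strength,
        no_clear_elbow=strength < FLAT_ELBOW_THRESHOLD,
    )
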