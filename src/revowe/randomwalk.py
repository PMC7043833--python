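"""N-dimensional biased random walk benchmark.

Walker conformations are length-N vectors of non-negative integers.  At
every dynamics step each dimension independently moves +1 with probability
``p_up`` (0.25 by default) or -1 otherwise; a move to -1 is rejected and
the component stays at 0.  With p_up = 0.25 the per-dimension stationary
distribution is geometric,

    P_t(x) = (2/3) * (1/3)**x,

which makes the system a benchmark with an exactly known target: positions
beyond x ~ 10 are astronomically rare for an unresampled walker, so a
resampler's ability to reach and weight them correctly is directly
measurable.  Distances between walkers use the dimension-scaled Manhattan
norm d(a, b) = (1/N) * sum_d |a_d - b_d|.

Each dimension evolves independently; only resampling couples them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import BoundaryCondition, Walker, WalkerEnsemble

__all__ = [
    "RWParams",
    "rw_step",
    "rw_distance",
    "rw_target_prob",
    "RandomWalkDistance",
    "RandomWalkDynamics",
    "make_initial_ensemble",
    "origin_return_boundary",
]


@dataclass(frozen=True)
class RWParams:
    """Random-walk system parameters.

    n_dims
        Dimensionality N of the lattice.
    p_up
        Forward-step probability per dimension per step (default 0.25,
        biasing the walk toward the origin).
    steps_per_cycle
        Dynamics steps between resampling calls (10 by default).
    """

    n_dims: int
    p_up: float = 0.25
    steps_per_cycle: int = 10

    def __post_init__(self) -> None:
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")
        if not (0.0 < self.p_up <= 1.0):
            # p_up = 1 (deterministic forward drift) is a useful degenerate
            # case for validation, so the closed upper endpoint is allowed.
            raise ValueError("p_up must lie in (0, 1]")
        if self.steps_per_cycle < 1:
            raise ValueError("steps_per_cycle must be >= 1")


def rw_step(
    state: np.ndarray, params: RWParams, rng: np.random.Generator, n_steps: int = 1
) -> np.ndarray:
    """Advance one walker by ``n_steps`` lattice steps.

    Each step draws one Bernoulli per dimension, in dimension order;
    backward moves at 0 are rejected (the component stays at 0), which is
    what produces the geometric stationary law.
    """
    pos = np.asarray(state, dtype=np.int64)
    if pos.shape != (params.n_dims,):
        raise ValueError("state has the wrong dimensionality")
    if np.any(pos < 0):
        raise ValueError("random-walk positions must be non-negative")
    for _ in range(n_steps):
        moves = np.where(rng.random(params.n_dims) < params.p_up, 1, -1)
        pos = np.maximum(pos + moves, 0)
    return pos


def rw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Scaled Manhattan distance (1/N) * sum_d |a_d - b_d|."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("states must share dimensionality")
    return float(np.abs(a - b).mean())


def rw_target_prob(x):
    """Analytic per-dimension stationary probability (2/3) * (1/3)**x."""
    arr = np.asarray(x)
    if np.any(arr < 0):
        raise ValueError("positions must be non-negative")
    out = (2.0 / 3.0) * (1.0 / 3.0) ** np.asarray(arr, dtype=float)
    return float(out) if np.isscalar(x) else out


class RandomWalkDistance:
    """Scaled-Manhattan metric with a vectorized all-to-all path."""

    def __call__(self, a, b) -> float:
        return rw_distance(a, b)

    def pairwise(self, states) -> np.ndarray:
        x = np.asarray(states, dtype=float)
        n_dims = x.shape[1]
        return squareform(pdist(x, metric="cityblock")) / n_dims


class RandomWalkDynamics:
    """Ensemble dynamics: ``steps_per_cycle`` biased lattice steps.

    Random draws are consumed step-major, then walker, then dimension, so
    a seeded run is bit-reproducible.
    """

    def __init__(self, params: RWParams):
        self.params = params

    def __call__(
        self, ensemble: WalkerEnsemble, rng: np.random.Generator
    ) -> WalkerEnsemble:
        pos = np.asarray(ensemble.states(), dtype=np.int64)
        p_up = self.params.p_up
        for _ in range(self.params.steps_per_cycle):
            moves = np.where(rng.random(pos.shape) < p_up, 1, -1)
            pos = np.maximum(pos + moves, 0)
        walkers = [
            Walker(pos[i].copy(), w.weight)
            for i, w in enumerate(ensemble.walkers)
        ]
        return WalkerEnsemble(walkers, ensemble.cycle_index)


def make_initial_ensemble(n_walkers: int, n_dims: int) -> WalkerEnsemble:
    """All walkers at the origin with equal weight 1/n."""
    if n_walkers < 1:
        raise ValueError("need at least one walker")
    weight = 1.0 / n_walkers
    return WalkerEnsemble(
        [Walker(np.zeros(n_dims, dtype=np.int64), weight) for _ in range(n_walkers)]
    )


def origin_return_boundary(threshold: float, n_dims: int) -> BoundaryCondition:
    """Toy boundary: warp to the origin once the scaled-Manhattan distance
    from the origin reaches ``threshold``.

    Plays the role of the "unbound state" in ligand unbinding: the warped
    weight accumulates into the reactive flux.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    origin = np.zeros(n_dims, dtype=np.int64)

    def predicate(state) -> bool:
        return rw_distance(state, origin) >= threshold

    return BoundaryCondition(predicate=predicate, warp_state=origin)
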