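"""Synthetic walker ensembles for distance-exponent (alpha) calibration.

Choosing REVO's distance exponent alpha does not require new simulations:
one evaluates the variation of "early" and "late" walker ensembles taken
from an existing run and picks an alpha that separates them.  Early
ensembles (few cycles in) have tight pairwise distances and near-uniform,
high weights; late ensembles are bimodal -- a cluster still near the
start plus a far cluster of low-weight walkers that have reached the rare
state, with weights within a few orders of magnitude of p_min.

This module generates synthetic ensembles with exactly those geometric
and weight signatures (distance matrices come from embedded points, so
they are symmetric, zero-diagonal and satisfy the triangle inequality).
They emulate the *structure* of ligand-unbinding ensembles, not any
particular molecular system.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["generate_calibration_ensembles"]


def generate_calibration_ensembles(
    kind: str,
    n_walkers: int = 48,
    seed: int = 0,
    d0: float = 1.0,
    p_min: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic (weights, distance matrix) calibration ensemble.

    kind
        ``"early"``: all pairwise distances below d0, all weights within
        10% of 1/n.
        ``"late"``: a quarter of the walkers sit in a far cluster at
        ~10*d0 (guaranteeing pairs beyond 5*d0) with log-uniform weights
        in [100*p_min, 1e-6], at least one below 1e-8; the remaining
        weight stays on the near cluster.

    Weights sum to 1; the construction invariants are asserted.
    """
    if kind not in ("early", "late"):
        raise ValueError(f"kind must be 'early' or 'late', got {kind!r}")
    if n_walkers < 2:
        raise ValueError("need at least two walkers")
    rng = np.random.default_rng(seed)

    if kind == "early":
        # Compact cloud: 3-d Gaussian with sigma = 0.1*d0 keeps the
        # largest pairwise distance safely below d0 for n ~ 48.
        points = rng.normal(scale=0.1 * d0, size=(n_walkers, 3))
        dmat = squareform(pdist(points))
        weights = (1.0 + 0.1 * rng.uniform(-1.0, 1.0, size=n_walkers)) / n_walkers
        weights /= weights.sum()
        assert dmat.max() < d0, "early ensemble must stay within d0"
        assert weights.min() > 1e-3
    else:
        n_far = max(2, n_walkers // 4)
        n_near = n_walkers - n_far
        near = rng.normal(scale=0.15 * d0, size=(n_near, 3))
        far_center = np.array([10.0 * d0, 0.0, 0.0])
        far = far_center + rng.normal(scale=0.25 * d0, size=(n_far, 3))
        points = np.vstack([near, far])
        dmat = squareform(pdist(points))
        # Far walkers carry rare-event weight: log-uniform over
        # [100*p_min, 1e-6], forced to include something below 1e-8.
        lo, hi = np.log10(100.0 * p_min), -6.0
        far_w = 10.0 ** rng.uniform(lo, hi, size=n_far)
        far_w[0] = 10.0 ** rng.uniform(lo, -9.0)
        near_w = 1.0 + 0.2 * rng.uniform(-1.0, 1.0, size=n_near)
        near_w *= (1.0 - far_w.sum()) / near_w.sum()
        weights = np.concatenate([near_w, far_w])
        assert dmat.max() > 5.0 * d0, "late ensemble must reach beyond 5*d0"
        assert weights.min() < 1e-8
        assert weights.min() >= p_min

    assert abs(weights.sum() - 1.0) < 1e-12
    return weights, dmat
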