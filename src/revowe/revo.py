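"""REVO: resampling of ensembles by variation optimization.

REVO is a region-free weighted-ensemble resampler.  Instead of binning
conformation space, it greedily maximizes the *trajectory variation*

    V = sum_i V_i = sum_i sum_j (d_ij / d0)^alpha * phi_i * phi_j

where ``d_ij`` is the all-to-all pairwise distance between walkers under a
system-specific metric, ``d0`` is a characteristic distance that makes V
unit-free, ``alpha`` modulates how strongly large distances dominate, and
``phi_i`` is a per-walker *novelty*.  The weight-based novelty

    phi_i = ln(w_i) - ln(p_min / 100)

prioritizes high-weight walkers (for p_min = 1e-12 it runs from ~32 at
w = 1 down to ln(100) = 4.6 at w = p_min).

Each resampling call repeats a greedy move -- clone the highest-V_i
eligible walker, merge the lowest-V_i walker with its nearest mergeable
neighbour -- and accepts it only if the recomputed variation strictly
increases, undoing and stopping otherwise.  Weight bounds p_min and p_max
cap how thin a walker may be split and how much probability one walker may
hoard (p_max = 0.1 guarantees at least 10 walkers of appreciable weight).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    Operation,
    ResamplingRecord,
    Walker,
    WalkerEnsemble,
    copy_state,
)

__all__ = [
    "REVOParams",
    "VariationResult",
    "novelty",
    "calc_variation",
    "validate_distance_matrix",
    "estimate_d0",
    "min_walkers_for_weight_cap",
    "REVOResampler",
    "revo_resample",
    "alpha_scan",
]


@dataclass(frozen=True)
class REVOParams:
    """REVO resampler parameters.

    alpha
        Distance exponent in the variation (>= 0, unitless).
    d0
        Characteristic distance, in the units of the distance metric;
        normalizes distances so V is unit-free.
    p_min, p_max
        Minimum and maximum statistical weight a walker may hold.
    merge_distance
        Maximum pairwise distance at which two walkers may be merged,
        bounding the information lost per merge.
    novelty_mode
        ``"weight_based"`` for the logarithmic weight novelty, or
        ``"constant"`` to set phi_i = 1 for all walkers.
    """

    alpha: float
    d0: float
    p_min: float = 1e-12
    p_max: float = 0.1
    merge_distance: float = 2.5
    novelty_mode: str = "weight_based"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not (0.0 < self.p_min < self.p_max <= 1.0):
            raise ValueError("require 0 < p_min < p_max <= 1")
        if not self.merge_distance > 0:
            raise ValueError("merge_distance must be positive")
        if self.novelty_mode not in ("weight_based", "constant"):
            raise ValueError(f"unknown novelty_mode {self.novelty_mode!r}")


@dataclass
class VariationResult:
    """Total variation, its per-walker decomposition and the novelties."""

    v_total: float
    v_i: np.ndarray
    phi_i: np.ndarray


def novelty(weight, p_min: float):
    """Weight-based novelty phi = ln(weight) - ln(p_min / 100).

    Strictly increasing in the weight; accepts scalars or arrays.  Weights
    below p_min are a contract violation (the resampler must never create
    one) and raise.
    """
    w = np.asarray(weight, dtype=float)
    if np.any(w < p_min):
        raise ValueError("weight below p_min passed to novelty")
    out = np.log(w) - math.log(p_min / 100.0)
    return float(out) if np.isscalar(weight) else out


def min_walkers_for_weight_cap(p_max: float) -> int:
    """Smallest walker count compatible with every weight <= p_max.

    Total weight is 1, so at least ceil(1 / p_max) walkers are needed;
    p_max = 0.1 guarantees at least 10 walkers of appreciable weight.
    """
    if not (0.0 < p_max <= 1.0):
        raise ValueError("p_max must lie in (0, 1]")
    return math.ceil(1.0 / p_max)


def validate_distance_matrix(dmat: np.ndarray) -> np.ndarray:
    """Check symmetry, zero diagonal and non-negativity; return as float array."""
    d = np.asarray(dmat, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(d < 0):
        raise ValueError("distance matrix has negative entries")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if not np.array_equal(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    return d


def calc_variation(
    weights, dmat, params: REVOParams, *, validate: bool = False
) -> VariationResult:
    """Evaluate the variation V and its per-walker terms V_i.

    V_i = sum_j (d_ij / d0)^alpha * phi_i * phi_j with the i = j term
    contributing zero (d_ii = 0).
    """
    w = np.asarray(weights, dtype=float)
    d = validate_distance_matrix(dmat) if validate else np.asarray(dmat, dtype=float)
    if d.shape[0] != w.shape[0]:
        raise ValueError("distance matrix does not match the number of weights")
    if params.novelty_mode == "constant":
        phi = np.ones_like(w)
    else:
        phi = novelty(w, params.p_min)
    scaled = (d / params.d0) ** params.alpha
    np.fill_diagonal(scaled, 0.0)  # keeps the self-term out even for alpha = 0
    v_i = phi * (scaled @ phi)
    return VariationResult(v_total=float(v_i.sum()), v_i=v_i, phi_i=phi)


def _pairwise(states, distance) -> np.ndarray:
    """All-to-all distance matrix, using a vectorized metric when offered."""
    pairwise = getattr(distance, "pairwise", None)
    if pairwise is not None:
        return np.asarray(pairwise(states), dtype=float)
    n = len(states)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = distance(states[i], states[j])
    return d


def estimate_d0(states, distance) -> float:
    """Characteristic distance: mean pairwise distance over all walker pairs.

    Estimated from the ensemble after a single dynamics cycle.  An
    all-identical ensemble has no usable scale and raises.
    """
    n = len(states)
    if n < 2:
        raise ValueError("need at least two walkers to estimate d0")
    d = _pairwise(states, distance)
    iu = np.triu_indices(n, k=1)
    d0 = float(d[iu].mean())
    if d0 == 0.0:
        raise ValueError("all walkers identical: characteristic distance is zero")
    return d0


def _select_candidates(w, dmat, v_i, params: REVOParams):
    """Pick (clone, merge-low, merge-partner) slots for one greedy move.

    m1 is the lowest-V_i walker below p_max; m2 the walker closest to m1
    whose combined weight stays below p_max within the merge distance; c
    the highest-V_i walker (excluding m1, m2) whose children would stay at
    or above p_min.  Ties break to the lowest slot index.  Returns None if
    any role cannot be filled, which terminates the optimization loop.
    """
    n = w.shape[0]
    elig_m1 = w < params.p_max
    if not elig_m1.any():
        return None
    v_masked = np.where(elig_m1, v_i, np.inf)
    m1 = int(np.argmin(v_masked))

    dist_row = dmat[m1].copy()
    ok = (w + w[m1] < params.p_max) & (dist_row < params.merge_distance)
    ok[m1] = False
    if not ok.any():
        return None
    dist_row[~ok] = np.inf
    m2 = int(np.argmin(dist_row))

    elig_c = w / 2.0 >= params.p_min
    elig_c[m1] = elig_c[m2] = False
    if not elig_c.any():
        return None
    c = int(np.argmax(np.where(elig_c, v_i, -np.inf)))
    return c, m1, m2


class REVOResampler:
    """REVO resampler over a system-specific distance metric.

    ``distance`` is a callable ``(state_a, state_b) -> float``; if it also
    exposes ``pairwise(states)`` that vectorized path is used to build the
    all-to-all matrix.  Within the greedy loop the matrix is updated
    incrementally -- clones inherit their parent's row with zero distance
    inside the pair, merges keep the surviving walker's row -- which is
    exact because clone conformations are copies.
    """

    def __init__(self, distance, params: REVOParams):
        self.distance = distance
        self.params = params

    def resample(
        self, ensemble: WalkerEnsemble, rng: np.random.Generator
    ) -> tuple[WalkerEnsemble, ResamplingRecord]:
        params = self.params
        w = ensemble.weights
        states = [copy_state(s) for s in ensemble.states()]
        dmat = _pairwise(states, self.distance)

        res = calc_variation(w, dmat, params)
        v_initial = res.v_total
        v_old = v_initial
        ops: list[Operation] = []
        weights_before = w.copy()

        while True:
            cand = _select_candidates(w, dmat, res.v_i, params)
            if cand is None:
                break
            c, m1, m2 = cand

            # Tentative move: merge m1/m2 (freeing one slot), clone c into
            # its own slot plus the freed one.  Undo = discard the copies.
            combined = w[m1] + w[m2]
            keep_first = rng.random() < w[m1] / combined
            kept, freed = (m1, m2) if keep_first else (m2, m1)

            w_new = w.copy()
            w_new[kept] = combined
            half = w[c] / 2.0
            w_new[c] = half
            w_new[freed] = half

            d_new = dmat.copy()
            d_new[freed, :] = d_new[c, :]
            d_new[:, freed] = d_new[:, c]
            d_new[c, freed] = d_new[freed, c] = 0.0
            d_new[freed, freed] = 0.0

            res_new = calc_variation(w_new, d_new, params)
            if res_new.v_total > v_old:
                w, dmat, res, v_old = w_new, d_new, res_new, res_new.v_total
                states[freed] = copy_state(states[c])
                ops.append(Operation("merge", (m1, m2), (kept,), kept=kept))
                ops.append(Operation("clone", (c,), (c, freed)))
            else:
                break

        walkers = [Walker(states[i], float(w[i])) for i in range(len(w))]
        record = ResamplingRecord(
            cycle_index=ensemble.cycle_index,
            operations=ops,
            weights_before=weights_before,
            weights_after=w.copy(),
            info={
                "v_before": v_initial,
                "v_after": v_old,
                "n_moves": len(ops) // 2,
            },
        )
        return WalkerEnsemble(walkers, ensemble.cycle_index), record


def revo_resample(
    ensemble: WalkerEnsemble,
    dmat,
    params: REVOParams,
    rng: np.random.Generator,
) -> tuple[WalkerEnsemble, ResamplingRecord]:
    """Resample from a precomputed distance matrix (no metric required).

    Convenience wrapper over :class:`REVOResampler` for callers that hold
    walker ensembles plus pairwise distances but no conformation metric.
    """
    d = validate_distance_matrix(dmat)

    class _Frozen:
        def pairwise(self, states):
            return d

        def __call__(self, a, b):  # pragma: no cover - not used by resample
            raise NotImplementedError

    return REVOResampler(_Frozen(), params).resample(ensemble, rng)


def alpha_scan(
    ensembles,
    alphas,
    d0: float,
    *,
    p_min: float = 1e-12,
    novelty_mode: str = "weight_based",
) -> pd.DataFrame:
    """Mean variation per (label, alpha) over labeled walker ensembles.

    ``ensembles`` maps a label (e.g. ``"early"``/``"late"``) to a sequence
    of ``(weights, distance_matrix)`` pairs.  A single d0 is shared across
    labels and alphas so the variations stay comparable (d0 does not
    affect cloning/merging behaviour, only the scale of V).  Used to pick
    the distance exponent: an alpha that separates late (diverse,
    low-weight-tail) ensembles from early (compact) ones can drive the
    sampling toward the rare event.
    """
    rows = []
    for label, group in ensembles.items():
        group = list(group)
        if not group:
            raise ValueError(f"label {label!r} has no ensembles")
        for alpha in alphas:
            params = REVOParams(
                alpha=float(alpha), d0=d0, p_min=p_min, novelty_mode=novelty_mode
            )
            vals = [
                calc_variation(wts, dm, params, validate=True).v_total
                for wts, dm in group
            ]
            vals = np.asarray(vals)
            sem = (
                float(vals.std(ddof=1) / math.sqrt(len(vals)))
                if len(vals) > 1
                else float("nan")
            )
            rows.append(
                {
                    "label": label,
                    "alpha": float(alpha),
                    "mean_V": float(vals.mean()),
                    "sem_V": sem,
                }
            )
    return pd.DataFrame(rows, columns=["label", "alpha", "mean_V", "sem_V"])
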