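"""Post-run metrics for weighted-ensemble random-walk benchmarks.

Given run records (per-cycle walker positions and weights, plus warp
logs), this module computes:

* the predicted positional probability profile, averaged over dimensions,
  cycles and runs;
* the accuracy A = sum_x a(x), where each position contributes

      a(x) = 1 + |log Pt(x) - log P(x)| / log Pt(x)   if P(x) > Pt(x)^2
      a(x) = 0                                        otherwise

  so a(x) peaks at 1 exactly when P(x) = Pt(x) and positions whose
  estimate is worse than the square of the target contribute nothing
  (the condition is the strict log P > 2 log Pt, evaluated here as
  P > Pt^2 so the boundary lands on the zero branch in floating point);
* the sampling range (largest position visited per dimension, averaged);
* the run-to-run standard error of the probability profile;
* reactive flux and residence time from boundary-warp logs, with the
  residence time (mean first-passage time) taken as the reciprocal of the
  average probability flux;
* the distribution of walker distances to the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import WarpEvent

__all__ = [
    "ProbabilityProfile",
    "AccuracyResult",
    "RangeResult",
    "FluxSeries",
    "FluxResult",
    "OriginDistanceStats",
    "predicted_probability",
    "accuracy",
    "sampling_range",
    "run_standard_error",
    "flux_and_residence",
    "origin_distance_stats",
]


@dataclass
class ProbabilityProfile:
    """Estimated probability P(x) on the non-negative integers.

    ``probs[x]`` is the probability of position x; metadata records how
    many runs/cycles/dimensions were averaged.
    """

    probs: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        total = self.probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile sums to {total!r}, expected 1")

    def prob(self, x: int) -> float:
        return float(self.probs[x]) if 0 <= x < len(self.probs) else 0.0


@dataclass
class AccuracyResult:
    total: float
    contributions: np.ndarray  # a(x) for x = 0 .. max supported position


@dataclass
class RangeResult:
    mean: float
    sem: float
    per_run: np.ndarray


@dataclass
class FluxSeries:
    """Cumulative warped probability versus time for one run."""

    times: np.ndarray
    cumulative: np.ndarray

    @property
    def total(self) -> float:
        return float(self.cumulative[-1]) if len(self.cumulative) else 0.0


@dataclass
class FluxResult:
    series: list[FluxSeries]
    rates: np.ndarray
    mean_rate: float
    sem_rate: float
    residence_time: float
    residence_bounds: tuple[float, float]


@dataclass
class OriginDistanceStats:
    samples: np.ndarray
    weights: np.ndarray | None
    expectation: float


def _sampled_rows(n_cycles: int, burn_in_frac: float, sample_every: int) -> np.ndarray:
    """Row indices of the recorded snapshots that enter time averages.

    Row 0 is the initial ensemble; rows 1..n_cycles are post-cycle
    snapshots.  The first ``burn_in_frac`` of cycles (default 10%) is
    discarded.
    """
    burn_in = int(math.floor(burn_in_frac * n_cycles))
    rows = np.arange(burn_in + 1, n_cycles + 1, sample_every)
    if rows.size == 0:
        raise ValueError("burn-in leaves no cycles to average")
    return rows


def predicted_probability(
    records, burn_in_frac: float = 0.1, sample_every: int = 1
) -> ProbabilityProfile:
    """Average positional probability over dimensions, cycles and runs.

    For each sampled cycle the walker weights are histogrammed onto
    integer positions separately in every dimension (each dimension's
    histogram sums to 1 since the weights do); histograms are then
    averaged over dimensions, sampled cycles and runs.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one run record")
    n_dims = records[0].positions.shape[2]
    n_cycles = records[0].positions.shape[0] - 1
    for rec in records:
        if rec.positions.shape[2] != n_dims or rec.positions.shape[0] - 1 != n_cycles:
            raise ValueError("runs must share dimensionality and cycle count")
    max_x = int(max(rec.positions.max() for rec in records))
    rows = _sampled_rows(n_cycles, burn_in_frac, sample_every)

    acc = np.zeros(max_x + 1)
    for rec in records:
        hist = np.zeros(max_x + 1)
        for r in rows:
            pos = rec.positions[r]  # (n_walkers, n_dims)
            wts = np.repeat(rec.weights[r], n_dims)
            hist += np.bincount(pos.ravel(), weights=wts, minlength=max_x + 1)
        acc += hist / (len(rows) * n_dims)
    probs = acc / len(records)
    probs = probs / probs.sum()  # guard against float drift only
    return ProbabilityProfile(
        probs,
        meta={
            "n_dims": n_dims,
            "n_runs": len(records),
            "n_cycles_averaged": len(rows),
            "burn_in_frac": burn_in_frac,
        },
    )


def accuracy(profile: ProbabilityProfile, target=None) -> AccuracyResult:
    """Accuracy A = sum_x a(x) of a profile against the target law.

    Summed over x = 0 .. the largest position with P(x) > 0; the strict
    condition means positions with P(x) = 0, or estimates at or below
    Pt(x)^2, contribute zero.
    """
    if target is None:
        from .randomwalk import rw_target_prob

        target = rw_target_prob
    p = np.asarray(profile.probs, dtype=float)
    support = np.nonzero(p > 0)[0]
    if support.size == 0:
        return AccuracyResult(total=0.0, contributions=np.zeros(0))
    x_max = int(support[-1])
    p = p[: x_max + 1]
    pt = np.asarray([target(x) for x in range(x_max + 1)], dtype=float)
    cond = p > pt * pt  # == strict log P > 2 log Pt, exact at the boundary
    safe_p = np.where(cond, p, 1.0)
    a = np.where(
        cond,
        1.0 + np.abs(np.log(pt) - np.log(safe_p)) / np.log(pt),
        0.0,
    )
    return AccuracyResult(total=float(a.sum()), contributions=a)


def sampling_range(records) -> RangeResult:
    """Largest position visited per dimension, averaged over dimensions
    and then over runs (with the standard error across runs)."""
    records = list(records)
    if not records:
        raise ValueError("need at least one run record")
    per_run = np.array(
        [rec.positions.max(axis=(0, 1)).mean() for rec in records], dtype=float
    )
    sem = (
        float(per_run.std(ddof=1) / math.sqrt(len(per_run)))
        if len(per_run) > 1
        else float("nan")
    )
    return RangeResult(mean=float(per_run.mean()), sem=sem, per_run=per_run)


def run_standard_error(
    profiles, x_lo: int = 0, x_hi: int = 22
) -> float:
    """Average over x in [x_lo, x_hi] of the across-run SEM of P(x).

    Profiles shorter than the window are zero-padded (an unvisited
    position has estimated probability zero).
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two runs for a standard error")
    if x_hi < x_lo:
        raise ValueError("x_hi must be >= x_lo")
    width = x_hi - x_lo + 1
    mat = np.zeros((len(profiles), width))
    for r, prof in enumerate(profiles):
        p = np.asarray(prof.probs, dtype=float)
        for k, x in enumerate(range(x_lo, x_hi + 1)):
            mat[r, k] = p[x] if x < len(p) else 0.0
    sems = mat.std(axis=0, ddof=1) / math.sqrt(len(profiles))
    return float(sems.mean())


def flux_and_residence(
    warp_logs, n_cycles: int, cycle_duration: float = 1.0
) -> FluxResult:
    """Reactive flux and residence time from per-run warp logs.

    Each run's flux series is the cumulative warped weight versus time;
    its rate is total warped weight / total simulated time.  The mean
    rate over runs (with SEM) gives the residence time as 1 / mean rate
    (infinite when nothing warped).  ``residence_bounds`` propagates the
    SEM: (1 / (rate + sem), 1 / (rate - sem)).
    """
    if n_cycles <= 0 or cycle_duration <= 0:
        raise ValueError("run length must be positive")
    series: list[FluxSeries] = []
    rates = []
    duration = n_cycles * cycle_duration
    for events in warp_logs:
        events = sorted(events, key=lambda e: e.cycle_index)
        times = np.array([e.cycle_index * cycle_duration for e in events])
        cum = np.cumsum([e.warped_weight for e in events])
        series.append(FluxSeries(times=times, cumulative=np.asarray(cum, dtype=float)))
        total = float(cum[-1]) if len(cum) else 0.0
        rates.append(total / duration)
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("need at least one run")
    mean_rate = float(rates.mean())
    sem = (
        float(rates.std(ddof=1) / math.sqrt(rates.size))
        if rates.size > 1
        else float("nan")
    )
    residence = math.inf if mean_rate == 0.0 else 1.0 / mean_rate
    lo = math.inf if not (mean_rate + sem > 0) else 1.0 / (mean_rate + sem)
    hi = math.inf if not (mean_rate - sem > 0) else 1.0 / (mean_rate - sem)
    if math.isnan(sem):
        lo = hi = math.nan
    return FluxResult(
        series=series,
        rates=rates,
        mean_rate=mean_rate,
        sem_rate=sem,
        residence_time=residence,
        residence_bounds=(lo, hi),
    )


def origin_distance_stats(
    records,
    n_samples: int = 10,
    burn_in_frac: float = 0.1,
    weighted: bool = False,
) -> OriginDistanceStats:
    """Distribution of walker distances to the origin.

    Distances (scaled Manhattan, which for the origin is just the mean
    coordinate) are pooled over ``n_samples`` cycles spaced evenly through
    the post-burn-in part of each run and over all runs.  By default
    walkers pool uniformly; ``weighted=True`` weighs them by statistical
    weight instead.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one run record")
    samples = []
    wts = []
    for rec in records:
        n_cycles = rec.positions.shape[0] - 1
        burn_in = int(math.floor(burn_in_frac * n_cycles))
        rows = np.unique(
            np.linspace(max(burn_in, 1), n_cycles, n_samples).astype(int)
        )
        for r in rows:
            samples.append(rec.positions[r].mean(axis=1))
            wts.append(rec.weights[r])
    samples = np.concatenate(samples)
    if weighted:
        w = np.concatenate(wts)
        w = w / w.sum()
        return OriginDistanceStats(
            samples=samples, weights=w, expectation=float(np.dot(w, samples))
        )
    return OriginDistanceStats(
        samples=samples, weights=None, expectation=float(samples.mean())
    )
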