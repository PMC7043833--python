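"""Simulation driver: run configuration, the cycle loop, run records.

A run is fully specified by a :class:`RunConfig` (resampler choice and
parameters, random-walk system parameters, walker/cycle counts, seed, and
an optional toy boundary condition).  ``run_simulation`` executes the
dynamics -> boundary -> resampling loop and returns a self-contained
:class:`RunRecord`: identical config + seed gives a bit-identical record.

Randomness contract: the run seed feeds a ``numpy.random.SeedSequence``
which spawns two independent streams -- one consumed only by the
single-cycle probe that estimates REVO's characteristic distance d0, one
for the main loop.  Within each cycle the main stream is consumed by the
dynamics first (step-major, walker, dimension order) and then by the
resampler's merge keep-choices, in move order.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import NoResampler, ResamplingRecord, WarpEvent, run_cycle
from .randomwalk import (
    RandomWalkDistance,
    RandomWalkDynamics,
    RWParams,
    make_initial_ensemble,
    origin_return_boundary,
)
from .revo import REVOParams, REVOResampler, estimate_d0
from .wexplore import WExploreResampler

__all__ = ["RunConfig", "RunRecord", "run_simulation"]

logger = logging.getLogger(__name__)

_RESAMPLERS = ("revo", "wexplore", "conv")


@dataclass
class RunConfig:
    """Everything needed to reproduce one random-walk WE run."""

    resampler: str
    n_walkers: int
    n_cycles: int
    seed: int
    n_dims: int
    p_up: float = 0.25
    steps_per_cycle: int = 10
    # REVO parameters (alpha defaults to the value the calibration
    # procedure selects; d0 = None means "estimate from one probe cycle").
    alpha: float = 4.0
    d0: float | None = None
    p_min: float = 1e-100
    p_max: float = 0.1
    merge_distance: float = 2.5
    novelty_mode: str = "weight_based"
    # WExplore parameters (coarsest threshold first).
    thresholds: tuple[float, ...] = (16.0, 4.0, 1.0, 0.25)
    max_children: int = 10
    # Toy boundary condition: warp to the origin at this scaled-Manhattan
    # distance from the origin (None disables warping).
    boundary_distance: float | None = None

    def validate(self) -> None:
        if self.resampler not in _RESAMPLERS:
            raise ValueError(
                f"resampler must be one of {_RESAMPLERS}, got {self.resampler!r}"
            )
        if self.n_walkers < 1:
            raise ValueError("n_walkers must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        RWParams(self.n_dims, self.p_up, self.steps_per_cycle)  # validates
        if self.resampler == "revo":
            REVOParams(
                alpha=self.alpha,
                d0=self.d0 if self.d0 is not None else 1.0,
                p_min=self.p_min,
                p_max=self.p_max,
                merge_distance=self.merge_distance,
                novelty_mode=self.novelty_mode,
            )
        if self.resampler == "wexplore":
            if len(self.thresholds) < 1:
                raise ValueError("wexplore needs at least one threshold level")
            if not (0.0 < self.p_min < self.p_max <= 1.0):
                raise ValueError("require 0 < p_min < p_max <= 1")
        if self.boundary_distance is not None and not self.boundary_distance > 0:
            raise ValueError("boundary_distance must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.thresholds, list):
            cfg.thresholds = tuple(cfg.thresholds)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d


@dataclass
class RunRecord:
    """Self-contained record of one run.

    positions
        ``(n_cycles + 1, n_walkers, n_dims)`` integer array; row 0 is the
        initial ensemble, row c the ensemble after cycle c.
    weights
        ``(n_cycles + 1, n_walkers)`` float64 array, same layout.
    """

    config: dict
    positions: np.ndarray
    weights: np.ndarray
    resampling: list[ResamplingRecord] = field(default_factory=list)
    warps: list[WarpEvent] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return self.positions.shape[0] - 1


def _build_resampler(config: RunConfig, distance, probe_states):
    if config.resampler == "conv":
        return NoResampler(), {}
    if config.resampler == "revo":
        d0 = config.d0
        if d0 is None:
            d0 = estimate_d0(probe_states, distance)
        params = REVOParams(
            alpha=config.alpha,
            d0=d0,
            p_min=config.p_min,
            p_max=config.p_max,
            merge_distance=config.merge_distance,
            novelty_mode=config.novelty_mode,
        )
        return REVOResampler(distance, params), {"d0": d0}
    initial_image = np.zeros(config.n_dims, dtype=np.int64)
    resampler = WExploreResampler(
        distance,
        config.thresholds,
        initial_image,
        max_children=config.max_children,
        p_min=config.p_min,
        p_max=config.p_max,
    )
    return resampler, {}


def run_simulation(config: RunConfig) -> RunRecord:
    """Run the configured WE simulation and return its record."""
    config.validate()
    rw_params = RWParams(config.n_dims, config.p_up, config.steps_per_cycle)
    dynamics = RandomWalkDynamics(rw_params)
    distance = RandomWalkDistance()

    ss = np.random.SeedSequence(config.seed)
    probe_ss, main_ss = ss.spawn(2)
    rng = np.random.default_rng(main_ss)

    ensemble = make_initial_ensemble(config.n_walkers, config.n_dims)

    probe_states = None
    if config.resampler == "revo" and config.d0 is None:
        probe = dynamics(ensemble, np.random.default_rng(probe_ss))
        probe_states = probe.states()
    resampler, extras = _build_resampler(config, distance, probe_states)

    boundary = None
    if config.boundary_distance is not None:
        boundary = origin_return_boundary(config.boundary_distance, config.n_dims)

    n = config.n_walkers
    positions = np.zeros((config.n_cycles + 1, n, config.n_dims), dtype=np.int64)
    weights = np.zeros((config.n_cycles + 1, n), dtype=np.float64)
    positions[0] = np.asarray(ensemble.states())
    weights[0] = ensemble.weights

    resampling: list[ResamplingRecord] = []
    warps: list[WarpEvent] = []
    v_trace = []
    for cycle in range(1, config.n_cycles + 1):
        ensemble, record, cycle_warps = run_cycle(
            ensemble, dynamics, boundary, resampler, rng
        )
        positions[cycle] = np.asarray(ensemble.states())
        weights[cycle] = ensemble.weights
        resampling.append(record)
        warps.extend(cycle_warps)
        if "v_after" in record.info:
            v_trace.append(record.info["v_after"])
        logger.info(
            "cycle %d: moves=%s warps=%d %s",
            cycle,
            record.info.get("n_moves", 0),
            len(cycle_warps),
            (
                f"V={record.info['v_after']:.4g}"
                if "v_after" in record.info
                else f"regions={record.info.get('n_regions', '-')}"
            ),
        )

    if v_trace:
        extras["v_trace"] = np.asarray(v_trace)
    if config.resampler == "wexplore":
        extras["region_hierarchy"] = resampler.hierarchy.to_dict()
        extras["n_regions"] = resampler.hierarchy.n_regions()

    return RunRecord(
        config=config.to_dict(),
        positions=positions,
        weights=weights,
        resampling=resampling,
        warps=warps,
        extras=extras,
    )
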