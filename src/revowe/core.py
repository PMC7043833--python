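"""Core weighted-ensemble machinery.

A weighted-ensemble (WE) simulation propagates a set of *walkers* -- copies
of the system, each carrying a statistical weight -- through alternating
rounds of unbiased dynamics and *resampling* (cloning and merging).
Resampling redistributes computational effort without biasing ensemble
averages: cloning replaces a walker by two copies that each carry half the
parent's weight, and merging replaces two walkers by one that carries the
summed weight and inherits one of the two conformations, chosen with
probability proportional to weight.  Because weights are only ever split
and summed, any observable estimated as a weight-weighted average remains
unbiased under arbitrary resampling policies.

This module defines the walker/ensemble containers, the clone and merge
primitives, the replayable resampling audit trail, boundary-condition
"warping" (used for rare-event flux estimates) and the
dynamics -> boundary -> resampling cycle loop.  The walker count is held
constant through every resampling call.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Protocol

import numpy as np

__all__ = [
    "WEIGHT_ATOL",
    "WeightConservationError",
    "InvalidMergeError",
    "Walker",
    "WalkerEnsemble",
    "Operation",
    "ResamplingRecord",
    "replay_record",
    "BoundaryCondition",
    "WarpEvent",
    "clone_walker",
    "merge_walkers",
    "apply_boundary",
    "Resampler",
    "NoResampler",
    "run_cycle",
]

#: Absolute tolerance on |sum(weights) - 1|.  Violations raise; weights are
#: never silently renormalized, since conservation is a correctness signal.
WEIGHT_ATOL = 1e-12


class WeightConservationError(RuntimeError):
    """Total ensemble weight drifted from 1; indicates a resampler bug."""


class InvalidMergeError(ValueError):
    """Merging these walkers would create a weight above 1."""


def copy_state(state: Any) -> Any:
    """Copy a walker conformation (fast path for numpy arrays)."""
    if isinstance(state, np.ndarray):
        return state.copy()
    return _copy.deepcopy(state)


@dataclass
class Walker:
    """A system conformation plus its statistical weight.

    The state is opaque to the WE machinery; for the random-walk benchmark
    it is a non-negative integer vector of length N.
    """

    state: Any
    weight: float

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"walker weight must lie in (0, 1], got {self.weight!r}")

    def copy(self) -> "Walker":
        return Walker(copy_state(self.state), self.weight)


@dataclass
class WalkerEnsemble:
    """An ordered set of walkers whose weights sum to one."""

    walkers: list[Walker]
    cycle_index: int = 0

    def __post_init__(self) -> None:
        if not self.walkers:
            raise ValueError("ensemble needs at least one walker")
        if self.cycle_index < 0:
            raise ValueError("cycle_index must be non-negative")
        total = math.fsum(w.weight for w in self.walkers)
        if abs(total - 1.0) > WEIGHT_ATOL:
            raise WeightConservationError(
                f"ensemble weights sum to {total!r}, expected 1 within {WEIGHT_ATOL}"
            )

    def __len__(self) -> int:
        return len(self.walkers)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w.weight for w in self.walkers], dtype=float)

    def states(self) -> list[Any]:
        return [w.state for w in self.walkers]

    def copy(self) -> "WalkerEnsemble":
        return WalkerEnsemble([w.copy() for w in self.walkers], self.cycle_index)


@dataclass(frozen=True)
class Operation:
    """One resampling move, addressed by walker slot indices.

    kind
        ``"merge"``: ``sources`` are the two merged slots, ``targets`` the
        single slot holding the merged walker, and ``kept`` the source slot
        whose conformation survived.
        ``"clone"``: ``sources`` is the cloned slot, ``targets`` the two
        slots receiving the half-weight children.
    """

    kind: str
    sources: tuple[int, ...]
    targets: tuple[int, ...]
    kept: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("clone", "merge", "keep"):
            raise ValueError(f"unknown operation kind {self.kind!r}")
        if self.kind == "merge" and self.kept not in self.sources:
            raise ValueError("merge operation must keep one of its sources")


@dataclass
class ResamplingRecord:
    """Per-cycle audit trail of clone/merge decisions.

    Replaying ``operations`` on the pre-resampling ensemble reproduces the
    post-resampling ensemble exactly (see :func:`replay_record`).
    """

    cycle_index: int
    operations: list[Operation] = field(default_factory=list)
    weights_before: np.ndarray | None = None
    weights_after: np.ndarray | None = None
    info: dict = field(default_factory=dict)


def replay_record(pre: WalkerEnsemble, record: ResamplingRecord) -> WalkerEnsemble:
    """Re-apply a :class:`ResamplingRecord` to its pre-resampling ensemble.

    Merges temporarily free a slot which a paired clone then fills; the
    record must leave no slot empty.  The replayed weights are checked
    against ``record.weights_after`` bit-exactly when present.
    """
    slots: list[Walker | None] = [w.copy() for w in pre.walkers]
    for op in record.operations:
        if op.kind == "merge":
            a, b = op.sources
            wa, wb = slots[a], slots[b]
            if wa is None or wb is None:
                raise ValueError("merge refers to an empty slot")
            combined = wa.weight + wb.weight
            kept_walker = slots[op.kept]
            merged = Walker(copy_state(kept_walker.state), combined)
            freed = b if op.kept == a else a
            (target,) = op.targets
            slots[target] = merged
            if freed != target:
                slots[freed] = None
        elif op.kind == "clone":
            (src,) = op.sources
            parent = slots[src]
            if parent is None:
                raise ValueError("clone refers to an empty slot")
            half = parent.weight / 2.0
            state = parent.state
            for t in op.targets:
                slots[t] = Walker(copy_state(state), half)
        elif op.kind == "keep":
            pass
    if any(s is None for s in slots):
        raise ValueError("record leaves empty walker slots after replay")
    post = WalkerEnsemble([s for s in slots if s is not None], record.cycle_index)
    if record.weights_after is not None:
        if not np.array_equal(post.weights, np.asarray(record.weights_after)):
            raise ValueError("replayed weights differ from recorded weights_after")
    return post


@dataclass
class BoundaryCondition:
    """A warp rule: walkers satisfying ``predicate`` reset to ``warp_state``.

    Used to harvest rare-event flux: e.g. a walker whose ligand leaves the
    binding site is returned to the bound state and its weight is logged.
    """

    predicate: Callable[[Any], bool]
    warp_state: Any

    def __post_init__(self) -> None:
        if self.predicate(self.warp_state):
            raise ValueError("warp_state must not itself satisfy the boundary predicate")


@dataclass(frozen=True)
class WarpEvent:
    """A single warp: which walker, when, and how much probability crossed."""

    cycle_index: int
    walker_index: int
    warped_weight: float

    def __post_init__(self) -> None:
        if not (0.0 < self.warped_weight <= 1.0):
            raise ValueError("warped_weight must lie in (0, 1]")


def clone_walker(w: Walker) -> tuple[Walker, Walker]:
    """Split a walker into two copies carrying half the weight each.

    The children's weights sum to the parent's bit-exactly (w/2 + w/2).
    """
    half = w.weight / 2.0
    return Walker(copy_state(w.state), half), Walker(copy_state(w.state), half)


def merge_walkers(
    a: Walker, b: Walker, rng: np.random.Generator
) -> tuple[Walker, int]:
    """Merge two walkers into one of combined weight.

    The surviving conformation is ``a``'s with probability
    ``w_a / (w_a + w_b)``, else ``b``'s.  Returns the merged walker and
    which input was kept (0 for ``a``, 1 for ``b``) for the audit trail.
    """
    combined = a.weight + b.weight
    if combined > 1.0:
        raise InvalidMergeError(f"combined weight {combined!r} exceeds 1")
    kept = 0 if rng.random() < a.weight / combined else 1
    source = a if kept == 0 else b
    return Walker(copy_state(source.state), combined), kept


def apply_boundary(
    ens: WalkerEnsemble, bc: BoundaryCondition
) -> tuple[WalkerEnsemble, list[WarpEvent]]:
    """Warp every walker whose state satisfies the boundary predicate.

    Warped walkers keep their weight (the weight is what gets *logged*, not
    removed); total weight is conserved.  Each walker is checked once per
    call -- a freshly warped walker is not re-examined.
    """
    events: list[WarpEvent] = []
    walkers: list[Walker] = []
    for i, w in enumerate(ens.walkers):
        if bc.predicate(w.state):
            events.append(WarpEvent(ens.cycle_index, i, w.weight))
            walkers.append(Walker(copy_state(bc.warp_state), w.weight))
        else:
            walkers.append(w.copy())
    return WalkerEnsemble(walkers, ens.cycle_index), events


class Resampler(Protocol):
    """Anything that redistributes walkers while conserving weight/count."""

    def resample(
        self, ensemble: WalkerEnsemble, rng: np.random.Generator
    ) -> tuple[WalkerEnsemble, ResamplingRecord]:
        ...


class NoResampler:
    """Conventional baseline (CONV): dynamics only, no cloning or merging."""

    def resample(
        self, ensemble: WalkerEnsemble, rng: np.random.Generator
    ) -> tuple[WalkerEnsemble, ResamplingRecord]:
        w = ensemble.weights
        record = ResamplingRecord(
            cycle_index=ensemble.cycle_index,
            operations=[],
            weights_before=w,
            weights_after=w.copy(),
        )
        return ensemble, record


def run_cycle(
    ensemble: WalkerEnsemble,
    dynamics: Callable[[WalkerEnsemble, np.random.Generator], WalkerEnsemble],
    boundary: BoundaryCondition | None,
    resampler: Resampler,
    rng: np.random.Generator,
) -> tuple[WalkerEnsemble, ResamplingRecord, list[WarpEvent]]:
    """One WE cycle: dynamics, then boundary warping, then resampling.

    The boundary is applied *before* resampling so that the resampler sees
    the warped conformations.  Walker count and total weight are verified
    end-to-end; violations raise rather than being papered over.
    """
    n = len(ensemble)
    moved = dynamics(ensemble, rng)
    if len(moved) != n:
        raise RuntimeError("dynamics changed the walker count")
    warps: list[WarpEvent] = []
    if boundary is not None:
        moved, warps = apply_boundary(moved, boundary)
    post, record = resampler.resample(moved, rng)
    if len(post) != n:
        raise RuntimeError("resampler changed the walker count")
    total = math.fsum(w.weight for w in post.walkers)
    if abs(total - 1.0) > WEIGHT_ATOL:
        raise WeightConservationError(f"cycle left total weight {total!r}")
    new_cycle = ensemble.cycle_index + 1
    post = WalkerEnsemble(post.walkers, new_cycle)
    record.cycle_index = new_cycle
    warps = [WarpEvent(new_cycle, e.walker_index, e.warped_weight) for e in warps]
    return post, record, warps
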