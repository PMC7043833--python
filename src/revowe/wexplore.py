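"""Reference WExplore resampler: hierarchical Voronoi regions.

WExplore guides cloning and merging with a dynamically grown hierarchy of
Voronoi regions.  Each region is defined by an "image" -- a stored
conformation -- and a walker belongs to the region whose image is nearest.
Regions are nested: the hierarchy has one distance threshold per level,
ordered coarsest (largest threshold) first.  When a sampled conformation
is farther than a level's threshold from every image at that level (and
the parent is not at its branching cap), a new region is founded there
with the walker's conformation as image; images never move or disappear.

Resampling equalizes walker *counts* across sibling regions, working from
the top of the hierarchy downwards.  Moving one walker's worth of sampling
from an over-populated to an under-populated sibling is realized as one
merge (of the two lowest-weight same-leaf walkers in the donor) plus one
clone (of the highest-weight walker in the recipient).  Two walkers are
only ever merged if they share the same region at every level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import (
    Operation,
    ResamplingRecord,
    Walker,
    WalkerEnsemble,
    copy_state,
)

__all__ = [
    "RegionNode",
    "RegionHierarchy",
    "assign_walker",
    "update_regions",
    "wexplore_resample",
    "WExploreResampler",
]


@dataclass
class RegionNode:
    """One Voronoi region: a stored image conformation plus children."""

    image: Any
    level: int
    children: list["RegionNode"] = field(default_factory=list)


class RegionHierarchy:
    """A leveled tree of Voronoi regions with per-level thresholds.

    Thresholds are stored strictly decreasing (coarsest level first); a
    sequence given in any order is sorted.  The hierarchy starts with a
    single root-to-leaf chain built from the initial conformation, and can
    hold at most ``max_children ** n_levels`` leaf regions.
    """

    def __init__(self, thresholds, initial_image, max_children: int = 10):
        thr = sorted((float(t) for t in thresholds), reverse=True)
        if not thr:
            raise ValueError("need at least one threshold level")
        if len(set(thr)) != len(thr) or any(t <= 0 for t in thr):
            raise ValueError("thresholds must be positive and distinct")
        self.thresholds: tuple[float, ...] = tuple(thr)
        self.max_children = int(max_children)
        if self.max_children < 1:
            raise ValueError("max_children must be >= 1")
        # Virtual root at level -1; its children are the top-level regions.
        self._root = RegionNode(image=None, level=-1)
        self._grow_chain(self._root, copy_state(initial_image))

    @property
    def n_levels(self) -> int:
        return len(self.thresholds)

    @property
    def root(self) -> RegionNode:
        return self._root

    def _grow_chain(self, parent: RegionNode, image) -> RegionNode:
        """Found a region under ``parent`` and at every level below it."""
        node = parent
        for level in range(parent.level + 1, self.n_levels):
            child = RegionNode(image=copy_state(image), level=level)
            node.children.append(child)
            node = child
        return node

    def n_regions(self) -> int:
        """Number of leaf regions currently defined."""

        def count(node: RegionNode) -> int:
            if node.level == self.n_levels - 1:
                return 1
            return sum(count(c) for c in node.children)

        return count(self._root)

    def region_counts_per_level(self) -> list[int]:
        counts = [0] * self.n_levels
        stack = [self._root]
        while stack:
            node = stack.pop()
            for c in node.children:
                counts[c.level] += 1
                stack.append(c)
        return counts

    def assign(self, state, distance) -> tuple[int, ...]:
        """Greedy top-down assignment: nearest child image at each level.

        Returns the path of child indices from the top level to the leaf.
        Ties go to the lowest index (numpy argmin keeps the first).
        """
        path = []
        node = self._root
        for _level in range(self.n_levels):
            if not node.children:
                raise ValueError("hierarchy path ends before the leaf level")
            dists = [distance(state, c.image) for c in node.children]
            idx = int(np.argmin(dists))
            path.append(idx)
            node = node.children[idx]
        return tuple(path)

    def update(self, state, distance) -> bool:
        """Create regions for a conformation beyond the level thresholds.

        Descends from the top; at the first level where the conformation
        is farther than the threshold from every sibling image and the
        parent is below its branching cap, a new region chain is founded
        down to the leaf level with the conformation as every image.
        Returns True if any region was created.
        """
        node = self._root
        for level in range(self.n_levels):
            dists = [distance(state, c.image) for c in node.children]
            idx = int(np.argmin(dists))
            if dists[idx] > self.thresholds[level] and len(node.children) < self.max_children:
                self._grow_chain(node, state)
                return True
            node = node.children[idx]
        return False

    def to_dict(self) -> dict:
        """Serializable snapshot (thresholds, tree structure, images)."""

        def node_dict(node: RegionNode) -> dict:
            image = node.image
            if isinstance(image, np.ndarray):
                image = image.tolist()
            return {
                "level": node.level,
                "image": image,
                "children": [node_dict(c) for c in node.children],
            }

        return {
            "thresholds": list(self.thresholds),
            "max_children": self.max_children,
            "tree": node_dict(self._root),
        }


def assign_walker(state, hierarchy: RegionHierarchy, distance) -> tuple[int, ...]:
    """Path of region indices (top level to leaf) for a conformation."""
    return hierarchy.assign(state, distance)


def update_regions(
    ensemble: WalkerEnsemble, hierarchy: RegionHierarchy, distance
) -> RegionHierarchy:
    """Found new regions for all walkers, in ensemble order, in place.

    The first walker beyond a threshold founds the region ("first founder
    wins"); later walkers see the new image and usually fall inside it.
    """
    for walker in ensemble.walkers:
        hierarchy.update(walker.state, distance)
    return hierarchy


def _best_merge_pair(idxs, weights, paths, p_max):
    """Two lowest-weight same-leaf walkers whose combined weight < p_max."""
    by_leaf: dict[tuple, list[int]] = {}
    for i in idxs:
        by_leaf.setdefault(paths[i], []).append(i)
    best = None
    for leaf_idxs in by_leaf.values():
        if len(leaf_idxs) < 2:
            continue
        two = sorted(leaf_idxs, key=lambda i: (weights[i], i))[:2]
        total = weights[two[0]] + weights[two[1]]
        if total >= p_max:
            continue
        key = (total, min(two))
        if best is None or key < best[0]:
            best = (key, tuple(sorted(two)))
    return None if best is None else best[1]


def _best_clone(idxs, weights, p_min):
    """Highest-weight walker whose half-weight children stay >= p_min."""
    elig = [i for i in idxs if weights[i] / 2.0 >= p_min]
    if not elig:
        return None
    return min(elig, key=lambda i: (-weights[i], i))


def wexplore_resample(
    ensemble: WalkerEnsemble,
    hierarchy: RegionHierarchy,
    distance,
    p_min: float,
    p_max: float,
    rng: np.random.Generator,
) -> tuple[WalkerEnsemble, ResamplingRecord]:
    """Balance walker counts across regions, top level downwards.

    Within each sibling group, while some pair of siblings differs in
    (subtree) walker count by more than one and a legal move exists, one
    merge in the most-populated sibling plus one clone in the least-
    populated sibling shifts a walker slot across.  Donor/recipient pairs
    are tried in count order so a blocked extreme pair does not stall the
    whole group.  Weight and walker count are conserved exactly.
    """
    update_regions(ensemble, hierarchy, distance)

    n = len(ensemble)
    weights = ensemble.weights
    states = [copy_state(s) for s in ensemble.states()]
    paths = [hierarchy.assign(states[i], distance) for i in range(n)]
    weights_before = weights.copy()
    ops: list[Operation] = []

    def balance(level: int, idxs: list[int]) -> None:
        groups: dict[int, list[int]] = {}
        for i in idxs:
            groups.setdefault(paths[i][level], []).append(i)
        if len(groups) > 1:
            while True:
                order = sorted(groups, key=lambda c: (len(groups[c]), c))
                move = None
                for donor in reversed(order):
                    for recipient in order:
                        if len(groups[donor]) - len(groups[recipient]) <= 1:
                            continue
                        pair = _best_merge_pair(groups[donor], weights, paths, p_max)
                        k = _best_clone(groups[recipient], weights, p_min)
                        if pair is not None and k is not None:
                            move = (donor, recipient, pair, k)
                            break
                    if move is not None:
                        break
                if move is None:
                    break
                donor, recipient, (i, j), k = move
                combined = weights[i] + weights[j]
                kept, freed = (
                    (i, j) if rng.random() < weights[i] / combined else (j, i)
                )
                weights[kept] = combined
                half = weights[k] / 2.0
                weights[k] = half
                weights[freed] = half
                states[freed] = copy_state(states[k])
                paths[freed] = paths[k]
                groups[donor].remove(freed)
                groups[recipient].append(freed)
                ops.append(Operation("merge", (i, j), (kept,), kept=kept))
                ops.append(Operation("clone", (k,), (k, freed)))
        if level + 1 < hierarchy.n_levels:
            for child in sorted(groups):
                balance(level + 1, groups[child])

    balance(0, list(range(n)))

    walkers = [Walker(states[i], float(weights[i])) for i in range(n)]
    total = math.fsum(weights)
    record = ResamplingRecord(
        cycle_index=ensemble.cycle_index,
        operations=ops,
        weights_before=weights_before,
        weights_after=weights.copy(),
        info={
            "n_regions": hierarchy.n_regions(),
            "n_moves": len(ops) // 2,
            "total_weight": total,
        },
    )
    return WalkerEnsemble(walkers, ensemble.cycle_index), record


class WExploreResampler:
    """WExplore resampler owning a mutable region hierarchy.

    The hierarchy grows across cycles as new conformations are sampled;
    the resampler object therefore carries run state, unlike REVO.
    """

    def __init__(
        self,
        distance,
        thresholds,
        initial_image,
        max_children: int = 10,
        p_min: float = 1e-12,
        p_max: float = 0.1,
    ):
        if not (0.0 < p_min < p_max <= 1.0):
            raise ValueError("require 0 < p_min < p_max <= 1")
        self.distance = distance
        self.p_min = p_min
        self.p_max = p_max
        self.hierarchy = RegionHierarchy(thresholds, initial_image, max_children)

    def resample(
        self, ensemble: WalkerEnsemble, rng: np.random.Generator
    ) -> tuple[WalkerEnsemble, ResamplingRecord]:
        return wexplore_resample(
            ensemble, self.hierarchy, self.distance, self.p_min, self.p_max, rng
        )
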