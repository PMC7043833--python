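# Methods

## The weighted-ensemble framework

A weighted-ensemble (WE) simulation maintains `n` walkers, each a system
conformation with a statistical weight, with weights summing to one.  A run
alternates two steps per cycle: unbiased dynamics that move every walker
forward, and a *resampling* step that clones "interesting" walkers (two
copies, half the weight each) and merges uninteresting ones (summed weight;
the surviving conformation is drawn proportionally to weight).  Because
weights are only split and summed, weight-weighted observables remain
unbiased for any resampling policy.  This package keeps the walker count
constant through every resampling call, conserves total weight to within
1e-12 (violations raise rather than being renormalized away), and logs every
clone/merge decision in a replayable per-cycle record.

An optional boundary condition is applied after dynamics and before
resampling: a walker whose state satisfies the boundary predicate is
"warped" back to the initial state, and its (unchanged) weight is logged.
The accumulated warped weight per unit time estimates the reactive flux;
its reciprocal estimates the mean first-passage time (for ligand unbinding,
the residence time).  Each walker is checked once per cycle; a freshly
warped walker is treated as an ordinary walker for the rest of the cycle.

## REVO

REVO is a region-free resampler.  Given the all-to-all pairwise distances
`d_ij` between walkers under a system-specific metric, it defines the
trajectory variation

    V = sum_i V_i,    V_i = sum_j (d_ij / d0)^alpha * phi_i * phi_j

and greedily maximizes it.  The pieces:

* **alpha** (unitless, default 4): modulates how strongly large distances
  dominate.  The calibration procedure below motivates the default.
* **d0** (characteristic distance): a normalization making V unit-free.  It
  is estimated as the mean pairwise walker distance after a single dynamics
  cycle, from a dedicated RNG substream so the main trajectory is unaffected.
  It has no influence on which walkers are cloned or merged.
* **phi_i** (novelty, default weight-based): `phi = ln(w) - ln(p_min/100)`,
  prioritizing high-weight walkers.  For `p_min = 1e-12` it spans ~32.24 at
  `w = 1` down to `ln 100 = 4.605` at `w = p_min`.  The natural logarithm and
  the reading of the constant 100 as a divisor of `p_min` are forced by those
  two anchor values.  `novelty_mode = "constant"` sets `phi = 1`, making the
  resampler weight-blind (useful for ablation; the sweep script exposes it).
* **p_min / p_max** (defaults 1e-100 / 0.1 for random-walk runs): weight
  floor and cap.  Cloning requires `w/2 >= p_min` — the literal eligibility
  rule `w > p_min` would let a clone create children below the floor, which
  the floor exists to prevent.  With `p_max = 0.1` at least
  `ceil(1/p_max) = 10` walkers always carry appreciable weight.
* **merge_distance** (default 2.5 in the metric's units): the maximum
  pairwise distance at which a merge is allowed, bounding information loss.

Each resampling call repeats a greedy move until it stops paying:

1. `m1` = lowest-`V_i` walker with `w < p_max`; `m2` = walker closest to
   `m1` with `w_m1 + w_m2 < p_max` and `d_{m1,m2} < merge_distance`;
   `c` = highest-`V_i` walker not in `{m1, m2}` with `w_c/2 >= p_min`.
   Choosing the merge pair first and excluding it from the clone choice
   keeps the three roles distinct; all ties break to the lowest slot index.
2. Merge `m1, m2` (freeing one slot) and clone `c` into its own slot plus
   the freed one, so the walker count never changes mid-loop.
3. Recompute V.  Accept if strictly greater, else undo (the tentative move
   is built on copies, so undo is free of side effects) and stop.

The distance matrix is updated incrementally inside the loop: a clone
duplicates its parent's row with distance 0 inside the pair, a merge keeps
the surviving walker's row.  Because cloned conformations are exact copies,
this equals a from-scratch re-evaluation of the metric bit-for-bit (asserted
in the tests), while avoiding O(n^2) metric calls per iteration.  The merge
keep-choice consumes one uniform draw per attempted move from the run's
RNG stream, so runs are bit-reproducible from the seed.

### Choosing alpha

Rather than sweeping alpha with full simulations, one evaluates V on
"early" ensembles (taken a few cycles into a run: tight distances, high
weights) and "late" ensembles (end of a run: a far cluster of low-weight
walkers that have reached the rare state) and picks an alpha that cleanly
separates them — if late ensembles do not score higher variation, maximizing
V cannot drive sampling toward the rare event.  `alpha_scan` tabulates mean
V per (label, alpha) with a single shared d0 (the early-ensemble estimate)
so values are comparable across labels.  On the synthetic calibration
ensembles below, the late-minus-early gap grows strictly with alpha over
1..4, which motivates the package default `alpha = 4`.

## WExplore (reference resampler)

WExplore guides resampling with a dynamically grown hierarchy of Voronoi
regions, each defined by a stored "image" conformation.  Thresholds are
ordered coarsest-first — for the random walk `(16, 4, 1, 0.25)`; the
constructor sorts whatever order it is given, since the hierarchy semantics
("progressively smaller thresholds") require it — with at most
`max_children = 10` children per node and four levels, hence at most 10^4
leaf regions.  Assignment descends greedily, nearest child image at each
level.  A walker farther than a level's threshold from every image at that
level founds a new region chain down to the leaf level (first founder in
ensemble order wins; images are exact copies and never move); at the
branching cap nothing is created.

Resampling equalizes walker counts across sibling groups, top level first.
A "move" merges the two lowest-weight same-leaf walkers in an over-populated
sibling (combined weight `< p_max`) and clones the highest-weight clonable
walker in an under-populated one; donor/recipient pairs are tried in count
order until no pair differing by more than one walker admits a legal move.
Merging is only ever between walkers sharing the same region at every
level.  Weight-extremal move choices are not dictated by the region rules;
they are chosen here because they minimize statistical distortion and are
deterministic.  Balancing uses region counts only, not weights.

## The biased random-walk benchmark

Walker states are length-N vectors of non-negative integers.  Per step and
per dimension the walker moves +1 with probability `p_up = 0.25`, else -1;
backward moves at 0 are rejected (the component stays), which yields the
per-dimension geometric stationary law `P_t(x) = (2/3)(1/3)^x`.  Ten steps
form one cycle.  Distances use the dimension-scaled Manhattan norm
`d(a,b) = (1/N) sum_d |a_d - b_d|`.  Dimensions are coupled only through
resampling, so the benchmark difficulty scales cleanly with N while the
target stays analytic.  The toy boundary condition warps a walker to the
origin once its scaled-Manhattan distance from the origin reaches a
threshold, standing in for the "unbound state" of an unbinding simulation.

## Analysis metrics

* **Predicted probability**: per sampled cycle, walker weights are
  histogrammed onto integer positions in each dimension; histograms are
  averaged over dimensions, cycles and runs.  Which cycles enter the
  average is not fixed by the method; the default discards the first 10%
  of cycles as burn-in and samples every cycle thereafter (configurable).
* **Accuracy**: `A = sum_x a(x)` with
  `a(x) = 1 + |log Pt - log P| / log Pt` when `log P > 2 log Pt`, else 0,
  summed from 0 to the largest visited position.  `a(x)` peaks at exactly 1
  when `P = Pt`.  The strict condition is evaluated as `P > Pt^2`, which is
  algebraically identical but puts the floating-point boundary case exactly
  on the zero branch; the log ratio itself is base-invariant (natural log
  used).
* **Range**: the largest position visited per dimension, averaged over
  dimensions, then over runs with a standard error.
* **Run-to-run standard error**: the across-run SEM of `P(x)`, averaged
  over a position window (default x in [0, 22]).
* **Flux / residence time**: per run, cumulative warped weight versus time;
  the per-run rate is total warped weight over total simulated time; the
  residence time is the reciprocal of the mean per-run rate (infinite when
  nothing warped), with SEM-propagated bounds.  For equal-length runs the
  mean of per-run rates equals pooled weight over pooled time.
* **Origin-distance statistics**: the distribution of walker distances to
  the origin pooled over 10 evenly spaced post-burn-in cycles and all runs.
  Walkers pool uniformly by default — the statistic describes where walkers
  *are*, not probability mass — with weight-weighted pooling as an option.

## Synthetic calibration ensembles

`generate_calibration_ensembles` builds (weights, distance-matrix) pairs
with the geometric/weight signature of early and late unbinding ensembles:
early — a compact Gaussian cloud (all pairwise distances below d0) with
weights within 10% of uniform; late — a quarter of the walkers displaced to
a cluster ~10 d0 away carrying log-uniform weights in [100 p_min, 1e-6]
(forced to include one below 1e-8), the rest keeping the remaining weight.
Distance matrices come from embedded points, so symmetry, zero diagonal and
the triangle inequality hold by construction.  These fixtures emulate the
*structure* that makes alpha selection work, not any molecular system; a
passing calibration test shows the variation separates such structures,
not that any particular ligand unbinds.

## What the benchmark tests do and do not show

The random walk has uncoupled dimensions, an analytic target and integer
states with an exact, cheap metric.  Passing the comparative tests shows
the resamplers redistribute sampling as designed (variation optimization
reaches farther positions than an unresampled run and is more consistent
across runs than region-based balancing); it does not show performance on
rough molecular landscapes, metric noise, or dynamics with memory.  The
comparative checks run at desk scale — 48 walkers, 1000 cycles, 3–5 seeds,
N = 2 or 5, chosen as the package's own test-budget conditions — and assert
orderings only, not the magnitudes that full-scale protocols (200 walkers,
10 000 cycles, 10 runs, N up to 20) would produce.

## Numerical choices and edge cases

* Weight arithmetic is double precision; clone halving and merge summation
  are exact; total-weight drift beyond 1e-12 raises.
* All candidate-selection ties (V_i, nearest-m2, merge pairs, clone picks,
  region assignment) break to the lowest index for determinism.
* `estimate_d0` raises on an all-identical ensemble (the variation is then
  undefined); `novelty` raises on a weight below `p_min` (a contract
  violation upstream).
* One seeded RNG stream drives a run; dynamics draws (step-major, walker,
  dimension order) precede resampler draws within each cycle.  d0
  estimation uses a separate spawned substream.
* Run records store every cycle's positions (int64) and weights (float64);
  HDF5 round-trips are bit-exact, and a JSON-lines fallback keeps records
  plain-text when needed.

## Known limitations

* Only constant walker counts are supported (resamplers that grow/shrink
  the ensemble are out of scope).
* No MD-engine integration or trajectory-format ingestion: the only
  built-in system is the lattice random walk, and external ensembles enter
  only as (weights, distance-matrix) pairs.
* The WExplore balancing move selection within a region (which walkers to
  merge/clone) is a deterministic design choice, not uniquely determined by
  the region-balancing description it implements.
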