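"""Unit tests for the REVO resampler: novelty, variation, greedy loop."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from revowe.calibration import generate_calibration_ensembles
from revowe.core import Walker, WalkerEnsemble, replay_record
from revowe.randomwalk import RandomWalkDistance
from revowe.revo import (
    REVOParams,
    REVOResampler,
    alpha_scan,
    calc_variation,
    estimate_d0,
    min_walkers_for_weight_cap,
    novelty,
    revo_resample,
)


def brute_force_variation(weights, dmat, alpha, d0, p_min):
    """Independent term-by-term evaluation of the variation sum."""
    n = len(weights)
    phi = [math.log(w) - math.log(p_min / 100.0) for w in weights]
    v_i = []
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j != i:
                s += (dmat[i][j] / d0) ** alpha * phi[i] * phi[j]
        v_i.append(s)
    return sum(v_i), v_i


class TestNovelty:
    def test_printed_anchors(self):
        # ln(1) - ln(1e-14) = 32.236... ; at w = p_min the value is ln(100)
        assert novelty(1.0, 1e-12) == pytest.approx(32.236, abs=1e-3)
        assert novelty(1e-12, 1e-12) == pytest.approx(math.log(100.0))

    def test_intermediate_value(self):
        # ln(1e-7 * 100 / 1e-12) = ln(1e7)
        assert novelty(1e-7, 1e-12) == pytest.approx(math.log(1e7))

    def test_monotone_in_weight(self):
        w = np.logspace(-12, 0, 50)
        phi = novelty(w, 1e-12)
        assert np.all(np.diff(phi) > 0)

    def test_below_p_min_rejected(self):
        with pytest.raises(ValueError):
            novelty(1e-13, 1e-12)


class TestVariation:
    def test_zero_distances_give_zero(self):
        params = REVOParams(alpha=4, d0=1.0)
        res = calc_variation([0.5, 0.5], np.zeros((2, 2)), params)
        assert res.v_total == 0.0
        assert np.all(res.v_i == 0.0)

    def test_two_walkers_at_d0(self):
        w = 0.5
        params = REVOParams(alpha=4, d0=2.0)
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        res = calc_variation([w, w], d, params)
        phi = novelty(w, params.p_min)
        assert res.v_i == pytest.approx([phi**2, phi**2])
        assert res.v_total == pytest.approx(2 * phi**2)

    def test_three_walker_frozen_oracle(self):
        w = [0.5, 0.3, 0.2]
        d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        params = REVOParams(alpha=4, d0=2.0, p_min=1e-12)
        res = calc_variation(w, d, params)
        v_ref, v_i_ref = brute_force_variation(w, d, 4.0, 2.0, 1e-12)
        assert res.v_total == pytest.approx(v_ref, rel=1e-12)
        assert res.v_i == pytest.approx(v_i_ref, rel=1e-12)
        # value frozen from the independent brute-force evaluation above
        assert res.v_total == pytest.approx(11804.556499531014, rel=1e-12)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scaling_invariance(self, scale):
        """Multiplying all distances and d0 by the same constant leaves V
        unchanged: the variation is unit-free by construction."""
        w = [0.4, 0.35, 0.25]
        d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        base = calc_variation(w, d, REVOParams(alpha=3, d0=1.5)).v_total
        scaled = calc_variation(
            w, d * scale, REVOParams(alpha=3, d0=1.5 * scale)
        ).v_total
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            calc_variation([0.5, 0.5], np.zeros((3, 3)), REVOParams(alpha=1, d0=1))


class TestCharacteristicDistance:
    def test_single_pair(self):
        dist = RandomWalkDistance()
        states = [np.array([0, 0]), np.array([4, 4])]
        assert estimate_d0(states, dist) == pytest.approx(4.0)

    def test_identical_walkers_rejected(self):
        dist = RandomWalkDistance()
        with pytest.raises(ValueError):
            estimate_d0([np.array([1, 1])] * 5, dist)

    def test_matches_bruteforce_pair_average(self, rw_ensemble):
        dist = RandomWalkDistance()
        states = rw_ensemble.states()
        d0 = estimate_d0(states, dist)
        n = len(states)
        acc, cnt = 0.0, 0
        for i in range(n):
            for j in range(i + 1, n):
                acc += dist(states[i], states[j])
                cnt += 1
        assert abs(d0 - acc / cnt) < 1e-12


def test_min_walkers_for_weight_cap():
    assert min_walkers_for_weight_cap(0.25) == 4
    assert min_walkers_for_weight_cap(0.3) == 4  # ceil(1/0.3)
    with pytest.raises(ValueError):
        min_walkers_for_weight_cap(0.0)


def _revo_on(ensemble, params, seed=11):
    dist = RandomWalkDistance()
    resampler = REVOResampler(dist, params)
    return resampler.resample(ensemble, np.random.default_rng(seed))


class TestResampleLoop:
    def test_no_merge_candidate_returns_input(self, rng):
        # every walker at p_max: no m1 exists, input returned unchanged
        ens = WalkerEnsemble([Walker(np.array([i, 0]), 0.1) for i in range(10)])
        params = REVOParams(alpha=4, d0=1.0, p_max=0.1)
        post, record = _revo_on(ens, params)
        assert record.operations == []
        assert np.array_equal(post.weights, ens.weights)

    def test_zero_distances_no_move_accepted(self):
        ens = WalkerEnsemble([Walker(np.array([2, 2]), 0.25) for _ in range(4)])
        params = REVOParams(alpha=4, d0=1.0)
        post, record = _revo_on(ens, params)
        assert record.operations == []
        assert record.info["v_before"] == record.info["v_after"] == 0.0

    def test_accepted_moves_strictly_increase_variation(self, rw_ensemble):
        """Replaying the record one clone+merge move at a time and
        re-evaluating the variation from the actual conformations shows a
        strictly increasing sequence of accepted V values."""
        dist = RandomWalkDistance()
        params = REVOParams(alpha=4, d0=1.0, p_min=1e-12)
        post, record = _revo_on(rw_ensemble, params)
        assert len(record.operations) >= 2, "instance should admit moves"

        states = [np.asarray(w.state).copy() for w in rw_ensemble.walkers]
        weights = rw_ensemble.weights.copy()
        v = calc_variation(weights, dist.pairwise(states), params).v_total
        assert v == record.info["v_before"]
        # operations come in (merge, clone) pairs, one pair per accepted move
        for k in range(0, len(record.operations), 2):
            merge_op, clone_op = record.operations[k], record.operations[k + 1]
            i, j = merge_op.sources
            kept = merge_op.kept
            freed = j if kept == i else i
            weights[kept] = weights[i] + weights[j]
            (c,) = clone_op.sources
            half = weights[c] / 2.0
            weights[c] = half
            weights[freed] = half
            states[freed] = states[c].copy()
            v_new = calc_variation(weights, dist.pairwise(states), params).v_total
            assert v_new > v
            v = v_new
        assert v == record.info["v_after"]

    def test_weight_bounds_and_conservation(self, rw_ensemble):
        params = REVOParams(alpha=4, d0=1.0, p_min=1e-4, p_max=0.1)
        post, record = _revo_on(rw_ensemble, params)
        w = post.weights
        assert len(post) == len(rw_ensemble)
        assert abs(math.fsum(w) - 1.0) < 1e-12
        assert w.max() <= params.p_max + 1e-15
        assert w.min() >= params.p_min

    def test_record_replays_to_post_ensemble(self, rw_ensemble):
        params = REVOParams(alpha=4, d0=1.0)
        post, record = _revo_on(rw_ensemble, params)
        replayed = replay_record(rw_ensemble, record)
        assert np.array_equal(replayed.weights, post.weights)
        assert all(
            np.array_equal(a.state, b.state)
            for a, b in zip(replayed.walkers, post.walkers)
        )

    def test_incremental_matrix_equals_full_recompute(self, rw_ensemble):
        """V from the incrementally updated matrix equals V recomputed
        from scratch on the post-move conformations, exactly."""
        dist = RandomWalkDistance()
        params = REVOParams(alpha=4, d0=1.0)
        post, record = _revo_on(rw_ensemble, params)
        res = calc_variation(post.weights, dist.pairwise(post.states()), params)
        assert res.v_total == record.info["v_after"]

    def test_constant_novelty_ignores_weight_permutation(self):
        """With phi = 1 the clone/merge slot selections depend only on the
        distances; permuting weights (kept well inside the p_min/p_max
        bounds) must not change them."""
        gen = np.random.default_rng(5)
        states = [np.array([i, (i * 3) % 7]) for i in range(8)]
        w = gen.dirichlet(np.ones(8)) * 0.2 + 0.1  # all in [0.1, 0.3]
        w = w / w.sum()
        perm = gen.permutation(8)
        params = REVOParams(
            alpha=4, d0=1.0, p_max=1.0, merge_distance=10.0, novelty_mode="constant"
        )
        ens_a = WalkerEnsemble([Walker(s, float(x)) for s, x in zip(states, w)])
        ens_b = WalkerEnsemble([Walker(s, float(x)) for s, x in zip(states, w[perm])])
        _, rec_a = _revo_on(ens_a, params, seed=9)
        _, rec_b = _revo_on(ens_b, params, seed=9)
        picks_a = [(op.kind, op.sources) for op in rec_a.operations]
        picks_b = [(op.kind, op.sources) for op in rec_b.operations]
        assert picks_a == picks_b


def test_revo_resample_from_matrix_matches_metric_path(rw_ensemble):
    """The precomputed-matrix wrapper and the metric-backed resampler make
    identical decisions for the same rng stream."""
    dist = RandomWalkDistance()
    params = REVOParams(alpha=4, d0=1.0)
    dmat = dist.pairwise(rw_ensemble.states())
    post_a, rec_a = revo_resample(rw_ensemble, dmat, params, np.random.default_rng(3))
    post_b, rec_b = REVOResampler(dist, params).resample(
        rw_ensemble, np.random.default_rng(3)
    )
    assert np.array_equal(post_a.weights, post_b.weights)
    assert [
        (o.kind, o.sources, o.targets) for o in rec_a.operations
    ] == [(o.kind, o.sources, o.targets) for o in rec_b.operations]


class TestAlphaScan:
    def test_identical_groups_have_ratio_one(self):
        w, d = generate_calibration_ensembles("early", 16, seed=1)
        table = alpha_scan({"a": [(w, d)], "b": [(w, d)]}, [1, 2, 3], d0=1.0)
        for alpha in (1, 2, 3):
            sub = table[table.alpha == alpha]
            va = sub[sub.label == "a"].mean_V.item()
            vb = sub[sub.label == "b"].mean_V.item()
            assert va == pytest.approx(vb)

    def test_table_matches_bruteforce(self):
        w = [0.6, 0.3, 0.1]
        d = np.array([[0.0, 0.5, 2.0], [0.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        table = alpha_scan({"only": [(np.array(w), d)]}, [1.0, 2.0], d0=1.0)
        for alpha in (1.0, 2.0):
            ref, _ = brute_force_variation(w, d, alpha, 1.0, 1e-12)
            got = table[(table.alpha == alpha)].mean_V.item()
            assert got == pytest.approx(ref, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            alpha_scan({"early": []}, [1], d0=1.0)
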