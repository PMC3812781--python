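"""Mixed continuous/discrete attractor: object-place retrieval, bump stability."""

import numpy as np
import pytest

from hipposim import cann
from hipposim.ca3 import LearningRule
from hipposim.cann import (
    CannNetwork,
    MixedMemory,
    bump_center,
    bump_stability,
    cann_recall,
    cann_store,
    mixed_pattern,
    train_manifold,
)


def _two_memory_net(sigma=20.0, seed=0):
    rng = np.random.default_rng(seed)
    set1 = frozenset(int(i) for i in rng.choice(500, 25, replace=False))
    rest = np.setdiff1d(np.arange(500), list(set1))
    set2 = frozenset(int(i) for i in rng.choice(rest, 25, replace=False))
    net = CannNetwork(1000, 500, k_continuous=int(4 * sigma), k_discrete=25)
    mems = [MixedMemory(300, sigma, set1), MixedMemory(500, sigma, set2)]
    return cann_store(net, mems), mems


class TestMixedPattern:
    def test_gaussian_closed_form(self):
        net = CannNetwork(1000, 500)
        mem = MixedMemory(300, 25.0, frozenset({0, 7}), peak_rate=2.0)
        r = mixed_pattern(mem, net)
        assert r[300] == pytest.approx(2.0)
        assert r[325] == pytest.approx(2.0 * np.exp(-0.5))
        assert r[1000] == 2.0 and r[1007] == 2.0  # discrete part

    def test_tiny_sigma_is_one_hot(self):
        net = CannNetwork(100, 0)
        r = mixed_pattern(MixedMemory(40, 1e-6), net)
        assert r[40] == 1.0
        assert np.count_nonzero(r > 1e-12) == 1

    def test_ring_wrapped_distance(self):
        net = CannNetwork(100, 0)
        r = mixed_pattern(MixedMemory(0, 10.0), net)
        assert r[99] == pytest.approx(r[1])


class TestStorage:
    def test_single_memory_is_fixed_point(self):
        net = CannNetwork(500, 200, k_continuous=80, k_discrete=10)
        mem = MixedMemory(100, 20.0, frozenset(range(10)))
        net = cann_store(net, [mem])
        full = mixed_pattern(mem, net)
        res = cann_recall(net, full, mode="completion")
        assert bump_center(res.continuous(net)) == pytest.approx(100, abs=2)
        np.testing.assert_array_equal(
            np.flatnonzero(res.discrete(net)), np.arange(10)
        )

    def test_storage_order_invariant(self):
        net = CannNetwork(300, 100)
        m1 = MixedMemory(50, 10.0, frozenset({1, 2}))
        m2 = MixedMemory(200, 10.0, frozenset({50, 51}))
        w_a = cann_store(net, [m1, m2]).w
        w_b = cann_store(net, [m2, m1]).w
        np.testing.assert_allclose(w_a, w_b, atol=1e-12)

    def test_distant_memories_nearly_uncoupled_under_covariance(self):
        net = CannNetwork(1000, 0)
        rule = LearningRule(variant="covariance", a_prior=0.05)
        net = cann_store(net, [MixedMemory(200, 15.0), MixedMemory(700, 15.0)], rule)
        # weights between the two bumps' cores come only from the tiny
        # mean-subtraction offsets, far smaller than within-bump weights
        # residual coupling comes only from the O(mean) subtraction offsets
        within = net.w[200, 210]
        across = abs(net.w[200, 700])
        assert across < 0.15 * within

    def test_no_self_connections(self):
        net, _ = _two_memory_net()
        assert np.all(np.diag(net.w) == 0)


class TestObjectPlaceRetrieval:
    def test_object_cue_retrieves_place(self):
        net, mems = _two_memory_net()
        for mem in mems:
            res = cann_recall(net, mixed_pattern(mem, net), mode="object-to-place")
            c = bump_center(res.continuous(net))
            err = min(abs(c - mem.center), 1000 - abs(c - mem.center))
            assert err <= 10

    def test_place_cue_retrieves_object(self):
        net, mems = _two_memory_net()
        for mem in mems:
            res = cann_recall(net, mixed_pattern(mem, net), mode="place-to-object")
            got = set(np.flatnonzero(res.discrete(net)).tolist())
            want = set(mem.discrete_set)
            jaccard = len(got & want) / len(got | want)
            assert jaccard >= 0.9

    def test_full_pattern_unchanged(self):
        net, mems = _two_memory_net()
        full = mixed_pattern(mems[0], net)
        res = cann_recall(net, full, mode="completion")
        assert bump_center(res.continuous(net)) == pytest.approx(300, abs=2)

    def test_accuracy_degrades_gracefully_with_load(self):
        # retrieval error is non-decreasing as more memories are stored
        sigma = 20.0
        rng = np.random.default_rng(3)
        centers = [100, 300, 500, 700, 900, 150, 350, 550]
        sets, pool = [], np.arange(500)
        for _ in centers:
            pick = rng.choice(pool, 20, replace=False)
            sets.append(frozenset(int(i) for i in pick))
            pool = np.setdiff1d(pool, pick)
        errs = []
        for n_mem in (2, 5, 8):
            net = CannNetwork(1000, 500, k_continuous=80, k_discrete=20)
            mems = [MixedMemory(c, sigma, s) for c, s in zip(centers[:n_mem], sets)]
            net = cann_store(net, mems)
            e = []
            for mem in mems:
                res = cann_recall(net, mixed_pattern(mem, net), mode="object-to-place")
                c = bump_center(res.continuous(net))
                e.append(min(abs(c - mem.center), 1000 - abs(c - mem.center)))
            errs.append(np.mean(e))
        assert errs[0] <= errs[-1] + 1e-9


class TestBumpStability:
    def test_bounded_drift(self):
        net = CannNetwork(1000, 0, k_continuous=80)
        net = train_manifold(net, sigma=20.0, spacing=10)
        traj = bump_stability(net, 300, 20.0, 200)
        drift = min(abs(traj[-1] - traj[0]), 1000 - abs(traj[-1] - traj[0]))
        assert drift <= 2.0

    def test_zero_iterations_zero_drift(self):
        net = CannNetwork(500, 0, k_continuous=60)
        net = train_manifold(net, sigma=15.0)
        traj = bump_stability(net, 100, 15.0, 0)
        assert traj.size == 1

    def test_single_bump_no_split(self):
        # the active continuous units stay circularly contiguous (one packet)
        net = CannNetwork(1000, 0, k_continuous=80)
        net = train_manifold(net, sigma=20.0)
        r = mixed_pattern(MixedMemory(300, 20.0), net)
        for _ in range(50):
            h = net.w @ r
            r = cann._joint_kwta(net, h)
            active = r[:1000] > 0
            gaps = np.diff(np.flatnonzero(active))
            # at most one gap larger than 1 position (the ring closure)
            assert (gaps > 1).sum() <= 1
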