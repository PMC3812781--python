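"""Diluted CA3 autoassociator: wiring, storage, retrieval, capacity."""

import math

import numpy as np
import pytest

from hipposim import ca3, patterns
from hipposim.ca3 import (
    LearningRule,
    RetrievalConfig,
    build_connectivity,
    capacity_analytic,
    capacity_simulated,
    duplicate_synapse_experiment,
    recall_auto,
    store_auto,
)


class TestConnectivity:
    def test_dilution_matches_rat_ratio(self):
        g = build_connectivity(1000, 40, seed=0)
        assert g.dilution == 0.04

    def test_no_autapses_no_duplicates(self):
        g = build_connectivity(300, 50, seed=1)
        for i in range(g.n):
            assert i not in g.afferents[i]
            assert np.unique(g.afferents[i]).size == g.c

    def test_forced_complete_digraph(self):
        g = build_connectivity(5, 4, seed=2)
        for i in range(5):
            assert sorted(g.afferents[i]) == sorted(set(range(5)) - {i})
        # as a set of unordered pairs the complete digraph is symmetric
        edges = {(i, j) for i in range(5) for j in g.afferents[i]}
        assert all((j, i) in edges for i, j in edges)

    def test_c_too_large_rejected(self):
        with pytest.raises(ValueError):
            build_connectivity(10, 10, seed=0, allow_multi=False)

    def test_seed_determinism(self):
        a = build_connectivity(100, 10, seed=3).afferents
        b = build_connectivity(100, 10, seed=3).afferents
        np.testing.assert_array_equal(a, b)


class TestStorage:
    def test_single_pattern_hebb_weights(self):
        g = build_connectivity(50, 10, seed=4)
        r = np.zeros(50)
        r[:10] = 1.0
        w = store_auto(r, g, LearningRule(k=1.0, variant="hebb"))
        both_active = (np.arange(50)[:, None] < 10) & (g.afferents < 10)
        np.testing.assert_array_equal(w.w, both_active.astype(float))

    def test_storage_additive(self):
        g = build_connectivity(100, 20, seed=5)
        ens = patterns.generate_binary_ensemble(100, 2, 0.1, seed=6)
        rule = LearningRule(a_prior=0.1)
        w_both = store_auto(ens, g, rule).w
        w_sum = store_auto(ens[0], g, rule).w + store_auto(ens[1], g, rule).w
        np.testing.assert_allclose(w_both, w_sum, atol=1e-12)

    def test_covariance_weights_average_near_zero(self):
        # over many random patterns the mean covariance weight is negligible
        # relative to the single-pattern weight scale a(1-a); a small negative
        # offset ~ a(1-a)/(N-1) remains because each pattern has an exactly
        # fixed active count
        g = build_connectivity(200, 40, seed=7)
        ens = patterns.generate_binary_ensemble(200, 500, 0.1, seed=8)
        w = store_auto(ens, g, LearningRule(a_prior=0.1))
        per_pattern_scale = 0.1 * 0.9
        mean_per_pattern = w.w.mean() / 500
        assert abs(mean_per_pattern) < 0.02 * per_pattern_scale

    def test_full_connectivity_covariance_symmetric(self):
        n = 40
        g = build_connectivity(n, n - 1, seed=9)
        ens = patterns.generate_binary_ensemble(n, 5, 0.2, seed=10)
        w = store_auto(ens, g, LearningRule(a_prior=0.2))
        dense = np.zeros((n, n))
        dense[np.repeat(np.arange(n), n - 1), g.afferents.ravel()] = w.w.ravel()
        np.testing.assert_allclose(dense, dense.T, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        g = build_connectivity(50, 10, seed=0)
        with pytest.raises(ValueError):
            store_auto(np.ones(49), g, LearningRule())


class TestRecall:
    def test_stored_pattern_is_fixed_point(self, small_net):
        graph, ens, w = small_net
        res = recall_auto(w, ens[0], RetrievalConfig(a_retrieval=0.05))
        assert patterns.overlap(res.state, ens[0]) >= 0.99
        assert res.converged

    def test_completion_from_half_cue(self, small_net):
        graph, ens, w = small_net
        cue = patterns.make_cue(ens[1], patterns.CueSpec(0.5, seed=20))
        res = recall_auto(w, cue, RetrievalConfig(a_retrieval=0.05))
        assert patterns.overlap(res.state, ens[1]) >= 0.95

    def test_toy_network_hand_computed(self):
        # N=8, two disjoint 2-active patterns, full connectivity, Hebb k=1:
        # w_ij = 1 iff i,j co-active. Cue = one unit of pattern A; drives are
        # h = w . cue + gain*cue, so the partner unit (h=1) and the cued unit
        # (h=gain) are the unique positive drives -> k-WTA returns pattern A.
        n = 8
        g = build_connectivity(n, n - 1, seed=0)
        pats = np.zeros((2, n))
        pats[0, [0, 1]] = 1.0
        pats[1, [2, 3]] = 1.0
        w = store_auto(pats, g, LearningRule(k=1.0, variant="hebb"))
        cue = np.zeros(n)
        cue[0] = 1.0
        res = recall_auto(w, cue, RetrievalConfig(a_retrieval=0.25, cue_gain=2.0))
        np.testing.assert_array_equal(res.state, pats[0])

    def test_asynchronous_update_runs(self, small_net):
        graph, ens, w = small_net
        cfg = RetrievalConfig(a_retrieval=0.05, update="asynchronous", seed=5)
        res = recall_auto(w, ens[0], cfg)
        assert patterns.overlap(res.state, ens[0]) >= 0.95

    def test_wrong_cue_length_rejected(self, small_net):
        graph, ens, w = small_net
        with pytest.raises(ValueError):
            recall_auto(w, np.ones(graph.n + 1), RetrievalConfig())


class TestAnalyticCapacity:
    def test_rat_parameters(self):
        est = capacity_analytic(12000, 0.02, 0.235)
        assert est.p_max == 36043  # "approximately 36,000"

    def test_prefactor_linearity(self):
        a = capacity_analytic(1000, 0.05, 0.1).p_max
        b = capacity_analytic(1000, 0.05, 0.2).p_max
        assert b == pytest.approx(2 * a, abs=1)

    def test_direct_arithmetic(self):
        assert capacity_analytic(100, 0.1, 0.25).p_max == 109

    def test_degenerate_sparseness_rejected(self):
        with pytest.raises(ValueError):
            capacity_analytic(100, 0.0, 0.2)
        with pytest.raises(ValueError):
            capacity_analytic(100, 1.0, 0.2)


class TestSimulatedCapacity:
    def test_capacity_positive_and_criterion_recorded(self):
        est = capacity_simulated(400, 60, 0.05, seed=0)
        assert est.p_max >= 1
        assert est.method == "simulated"
        assert "overlap" in est.criterion
        assert est.prefactor_k == pytest.approx(
            est.p_max * 0.05 * math.log(20) / 60
        )

    def test_overload_destroys_free_recall(self):
        # storing 3x the measured capacity wrecks the attractor landscape:
        # free dynamics (transient cue) lose most retrievable information
        n, c, a = 500, 80, 0.05
        est = capacity_simulated(n, c, a, seed=1)
        graph = build_connectivity(n, c, seed=2)
        ens = patterns.generate_binary_ensemble(n, 3 * est.p_max, a, seed=3)
        w = store_auto(ens, graph, LearningRule(a_prior=a))
        cfg = RetrievalConfig(a_retrieval=a, cue_gain=0.0)
        ovl = [
            patterns.overlap(recall_auto(w, ens[mu], cfg).state, ens[mu])
            for mu in range(0, 3 * est.p_max, max(1, est.p_max // 7))
        ]
        assert np.mean(ovl) < 0.5

    def test_desk_scale_guard(self):
        with pytest.raises(ValueError):
            capacity_simulated(5000, 100, 0.05)


class TestDuplicateSynapses:
    def test_zero_fraction_identical(self):
        rep = duplicate_synapse_experiment(300, 30, 0.05, 0.0, seed=0)
        assert rep.p_max_single == rep.p_max_multi

    def test_full_duplication_c2_degenerates(self):
        from hipposim.ca3 import _duplicate_wiring

        g = build_connectivity(50, 2, seed=1)
        gd = _duplicate_wiring(g, 1.0, seed=2)
        # every neuron ends with a single doubled afferent
        assert all(gd.afferents[i, 0] == gd.afferents[i, 1] for i in range(50))

    def test_duplicates_reduce_capacity(self):
        rep = duplicate_synapse_experiment(400, 60, 0.05, 0.3, seed=3)
        assert rep.p_max_multi < rep.p_max_single
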