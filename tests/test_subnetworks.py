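"""z-scoring, Monte-Carlo calibration and greedy active-subnetwork search."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import ndtr

import pathnetgwas as pg
from pathnetgwas import subnetworks as sn


class TestPToZ:
    def test_median_maps_to_zero(self):
        assert sn.p_to_z(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_three_sigma_point(self):
        # independent oracle: invert Phi by bisection
        lo, hi = 0.0, 10.0
        target = 1 - 0.0013499
        for _ in range(200):
            mid = (lo + hi) / 2
            if ndtr(mid) < target:
                lo = mid
            else:
                hi = mid
        assert sn.p_to_z(0.0013499) == pytest.approx(lo, abs=1e-9)
        assert sn.p_to_z(0.0013499) == pytest.approx(3.00, abs=1e-3)

    def test_p_one_is_clamped_finite_negative(self):
        z = sn.p_to_z(1.0)
        assert math.isfinite(z) and z < -8

    @given(st.floats(1e-290, 1.0), st.floats(1e-290, 1.0))
    def test_strictly_decreasing(self, p1, p2):
        if p1 == p2:
            assert sn.p_to_z(p1) == sn.p_to_z(p2)
        else:
            lo, hi = min(p1, p2), max(p1, p2)
            assert sn.p_to_z(lo) > sn.p_to_z(hi)


class TestAggregateZ:
    @pytest.mark.parametrize("zs, expected", [
        ([2, 2, 2, 2], 4.0),
        ([1.7], 1.7),
        ([1, -1], 0.0),
    ])
    def test_formula(self, zs, expected):
        assert sn.aggregate_z(zs) == pytest.approx(expected)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            sn.aggregate_z([])


class TestCalibration:
    def test_iid_normal_pool_has_unit_moments(self):
        rng = np.random.default_rng(5)
        pool = rng.standard_normal(100_000)
        calib = sn.calibrate(pool, sizes=[5, 25], n_samples=5_000, seed=3)
        for k in (5, 25):
            assert abs(calib.mu(k)) <= 0.08
            assert abs(calib.sigma(k) - 1.0) <= 0.08

    def test_constant_pool_gives_closed_form_mean_and_sigma_floor(self):
        calib = sn.calibrate(np.full(50, 2.0), sizes=[4], n_samples=200, seed=0)
        assert calib.mu(4) == pytest.approx(2.0 * math.sqrt(4))
        assert calib.sigma(4) == sn.SIGMA_FLOOR

    def test_same_seed_reproduces_table(self):
        pool = np.random.default_rng(1).standard_normal(200)
        c1 = sn.calibrate(pool, sizes=[3, 7], n_samples=500, seed=11)
        c2 = sn.calibrate(pool, sizes=[3, 7], n_samples=500, seed=11)
        assert c1.entries == c2.entries

    def test_size_exceeding_pool_is_error(self):
        with pytest.raises(ValueError):
            sn.calibrate(np.zeros(5), sizes=[6], n_samples=200, seed=0)

    def test_large_pool_rejection_path_matches_moments(self):
        rng = np.random.default_rng(2)
        pool = rng.standard_normal(500_000)  # triggers the rejection sampler
        calib = sn.calibrate(pool, sizes=[10], n_samples=2_000, seed=4)
        assert abs(calib.mu(10)) <= 0.1 and abs(calib.sigma(10) - 1) <= 0.1


class TestScore:
    def _calib(self):
        return sn.Calibration(entries={3: (1.5, 0.5, 100)}, rng_seed=0)

    def test_centering_and_scaling(self):
        z = sn.NodeZScores(entries={"a": 1.5 * math.sqrt(3) / 3} | {"b": 0.0, "c": 0.0})
        # construct z-values whose z_A equals mu exactly
        zv = {"a": 0.5, "b": 0.5, "c": 1.5981}
        z = sn.NodeZScores(entries=zv)
        z_a = sn.aggregate_z(list(zv.values()))
        got = sn.score({"a", "b", "c"}, z, self._calib())
        assert got.s_a == pytest.approx((z_a - 1.5) / 0.5)

    def test_missing_calibration_size_is_error(self):
        z = sn.NodeZScores(entries={"a": 1.0, "b": 1.0})
        with pytest.raises(KeyError):
            sn.score({"a", "b"}, z, self._calib())

    def test_null_scores_are_standard_normal(self):
        # Monte-Carlo oracle: random sets under the calibrated null give s_A ~ N(0,1)
        from scipy import stats

        rng = np.random.default_rng(9)
        pool = {f"n{i}": float(v) for i, v in enumerate(rng.standard_normal(400))}
        z = sn.NodeZScores(entries=pool)
        calib = sn.calibrate(z, sizes=[8], n_samples=20_000, seed=1)
        names = sorted(pool)
        draws = np.array([
            sn.score(rng.choice(names, 8, replace=False), z, calib).s_a
            for _ in range(1_000)
        ])
        assert stats.kstest(draws, "norm").pvalue > 0.01


def _graph_and_scores(rng_seed=42, planted=True):
    spec = pg.FixtureSpec(rng_seed=rng_seed, n_genes=200, planted_module_size=20)
    graph = pg.simulate_ppi(spec)
    pvals, truth = pg.plant_module(graph, spec)
    if not planted:
        pvals = {g: 1.0 for g in pvals}
    z = sn.NodeZScores.from_pvalues(pvals)
    calib = sn.calibrate(z, sizes=range(1, 101), n_samples=2_000, seed=rng_seed)
    return graph, z, calib, truth


class TestGreedySearch:
    def test_uniform_p_one_yields_nothing(self):
        graph, z, calib, _ = _graph_and_scores(planted=False)
        assert sn.greedy_search(graph, z, calib, score_cutoff=3.0, max_size=100) == []

    def test_planted_module_is_recovered(self):
        graph, z, calib, truth = _graph_and_scores()
        subnets = sn.greedy_search(graph, z, calib, score_cutoff=3.0, max_size=100)
        top = subnets[0]
        truth_set = truth.planted_gene_ids
        jaccard = len(top.node_ids & truth_set) / len(top.node_ids | truth_set)
        assert jaccard >= 0.5

    def test_every_result_meets_cutoff_and_is_connected(self):
        graph, z, calib, _ = _graph_and_scores()
        for subnet in sn.greedy_search(graph, z, calib, score_cutoff=3.0, max_size=100):
            assert subnet.s_a >= 3.0
            assert nx.is_connected(graph.subgraph(subnet.node_ids))
            assert subnet.k == len(subnet.node_ids)

    def test_search_is_deterministic(self):
        g1, z1, c1, _ = _graph_and_scores()
        g2, z2, c2, _ = _graph_and_scores()
        r1 = sn.greedy_search(g1, z1, c1, 3.0, 100)
        r2 = sn.greedy_search(g2, z2, c2, 3.0, 100)
        assert [(s.node_ids, s.s_a) for s in r1] == [(s.node_ids, s.s_a) for s in r2]

    def test_relabeling_equivariance(self):
        graph, z, calib, _ = _graph_and_scores()
        mapping = {n: f"X{n}" for n in graph.nodes}
        graph2 = nx.relabel_nodes(graph, mapping)
        z2 = sn.NodeZScores(entries={mapping[n]: v for n, v in z.entries.items()})
        r1 = sn.greedy_search(graph, z, calib, 3.0, 100)
        r2 = sn.greedy_search(graph2, z2, calib, 3.0, 100)
        relabeled = [frozenset(mapping[n] for n in s.node_ids) for s in r1]
        assert relabeled == [s.node_ids for s in r2]

    def test_unscored_neighbors_are_skipped(self):
        graph = nx.path_graph(["a", "b", "c"])
        z = sn.NodeZScores(entries={"a": 5.0, "b": 5.0})  # c unscored
        calib = sn.Calibration(
            entries={1: (0.0, 1.0, 100), 2: (0.0, 1.0, 100), 3: (0.0, 1.0, 100)},
            rng_seed=0,
        )
        results = sn.greedy_search(graph, z, calib, score_cutoff=3.0, max_size=3)
        assert results and results[0].node_ids == frozenset({"a", "b"})
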