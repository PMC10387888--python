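"""MCODE-style vertex weighting, dense clusters and pathway subnetwork search."""

import networkx as nx
import numpy as np
import pytest

import pathnetgwas as pg
from pathnetgwas.clustering import (
    McodeParams,
    PathwaySignificance,
    mcode_clusters,
    mcode_vertex_weights,
    pathway_subnetworks,
    subdivide_large,
)
from pathnetgwas.pathway_network import PathwayNetwork, build_pathway_network
from conftest import two_cliques_with_bridge


class TestVertexWeights:
    def test_k4_neighborhood_is_triangle(self):
        g = nx.relabel_nodes(nx.complete_graph(4), str)
        # every open neighborhood is a K3: core number 2, density 1 -> weight 2
        assert mcode_vertex_weights(g) == {n: 2.0 for n in g}

    def test_leaf_weight_zero(self):
        g = nx.path_graph(["a", "b", "c"])
        w = mcode_vertex_weights(g)
        assert w["a"] == 0.0 and w["c"] == 0.0

    def test_complete_graph_symmetry(self):
        g = nx.relabel_nodes(nx.complete_graph(7), str)
        assert len(set(mcode_vertex_weights(g).values())) == 1

    def test_isomorphism_invariance(self):
        g = two_cliques_with_bridge()
        w1 = mcode_vertex_weights(g)
        mapping = {n: f"Z{n}" for n in g}
        w2 = mcode_vertex_weights(nx.relabel_nodes(g, mapping))
        assert {mapping[n]: v for n, v in w1.items()} == w2


class TestMcodeClusters:
    def test_single_k4_is_one_cluster(self):
        g = nx.relabel_nodes(nx.complete_graph(4), str)
        clusters = mcode_clusters(g)
        assert len(clusters) == 1
        assert clusters[0].pathway_ids == frozenset(g.nodes)
        assert clusters[0].mcode_score == pytest.approx(4.0)  # density 1 x size 4

    def test_bridged_cliques_split_with_endpoints_retained(self):
        clusters = mcode_clusters(two_cliques_with_bridge())
        members = sorted(c.sorted_members() for c in clusters)
        assert members == [["a0", "a1", "a2", "a3", "a4"],
                           ["b0", "b1", "b2", "b3", "b4"]]

    def test_edgeless_graph_has_no_clusters(self):
        g = nx.empty_graph(["a", "b", "c"])
        assert mcode_clusters(g) == []

    def test_clusters_are_disjoint_connected_subgraphs(self):
        rng_graph = nx.gnp_random_graph(60, 0.12, seed=4)
        g = nx.relabel_nodes(rng_graph, lambda n: f"n{n:02d}")
        clusters = mcode_clusters(g)
        seen = set()
        for c in clusters:
            assert not (c.pathway_ids & seen)
            seen |= c.pathway_ids
            assert nx.is_connected(g.subgraph(c.pathway_ids))

    def test_haircut_removes_tree_extremities(self):
        g = nx.relabel_nodes(nx.complete_graph(4), str)
        g.add_edge("0", "tail")  # degree-1 appendage
        with_haircut = mcode_clusters(g, McodeParams(haircut=True))
        assert "tail" not in set().union(*(c.pathway_ids for c in with_haircut))

    def test_ranks_follow_scores(self):
        g = two_cliques_with_bridge()
        clusters = mcode_clusters(g)
        assert [c.rank for c in clusters] == [1, 2]
        assert clusters[0].mcode_score >= clusters[1].mcode_score


def _pnet_from_graph(g):
    return PathwayNetwork(graph=g, threshold=0.15)


class TestSubdivideLarge:
    def _subnet(self, nodes, k=None):
        from pathnetgwas.subnetworks import Subnetwork
        nodes = frozenset(nodes)
        return Subnetwork(node_ids=nodes, k=len(nodes), z_a=5.0, s_a=5.0,
                          seed_node=min(nodes))

    def test_small_subnetwork_returned_unchanged(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(40, 0.2, seed=1), lambda n: f"p{n:02d}")
        subnet = self._subnet(g.nodes)
        clusters = subdivide_large(subnet, _pnet_from_graph(g), size_threshold=50)
        assert len(clusters) == 1 and clusters[0].pathway_ids == subnet.node_ids

    def test_threshold_is_strictly_above_fifty(self):
        g = nx.relabel_nodes(nx.complete_graph(50), lambda n: f"p{n:02d}")
        subnet = self._subnet(g.nodes)
        clusters = subdivide_large(subnet, _pnet_from_graph(g), size_threshold=50)
        assert len(clusters) == 1 and len(clusters[0].pathway_ids) == 50

    def test_two_dense_blocks_are_separated(self):
        # 120 pathways: two 20-clique blocks plus sparse background
        g = nx.Graph()
        rng = np.random.default_rng(8)
        names = [f"p{i:03d}" for i in range(120)]
        g.add_nodes_from(names)
        for block in (names[:20], names[20:40]):
            for i, a in enumerate(block):
                for b in block[i + 1:]:
                    g.add_edge(a, b)
        others = names[40:]
        for _ in range(160):
            a, b = rng.choice(len(others), 2, replace=False)
            g.add_edge(others[a], others[b])
        g.add_edge(names[0], names[20])
        g.add_edge(names[5], names[41])
        # connect everything so the subnetwork is one component
        comps = list(nx.connected_components(g))
        for c1, c2 in zip(comps, comps[1:]):
            g.add_edge(sorted(c1)[0], sorted(c2)[0])
        subnet = self._subnet(g.nodes)
        clusters = subdivide_large(subnet, _pnet_from_graph(g), size_threshold=50)
        assert len(clusters) >= 2
        top_two = [c.pathway_ids for c in clusters[:2]]
        blocks = [set(names[:20]), set(names[20:40])]
        for block in blocks:
            assert any(len(block & c) / len(block) >= 0.8 for c in top_two)


class TestPathwaySubnetworks:
    def test_uniform_p_one_yields_nothing(self, default_bundle):
        pnet = build_pathway_network(default_bundle.collection)
        sig = PathwaySignificance(entries={p: 1.0 for p in pnet.graph.nodes})
        assert pathway_subnetworks(pnet, sig, cutoff=3.0, seed=2) == []

    def test_planted_cluster_is_recovered(self, default_bundle):
        pnet = build_pathway_network(default_bundle.collection)
        truth = default_bundle.truth
        sig = {p: 1.0 for p in pnet.graph.nodes}
        for p in truth.planted_pathway_ids:
            sig[p] = 1e-12
        subnets = pathway_subnetworks(pnet, PathwaySignificance(entries=sig),
                                      cutoff=3.0, seed=2)
        assert subnets, "planted pathway cluster not found"
        top = subnets[0]
        hit = len(top.node_ids & truth.planted_pathway_ids)
        assert hit / len(truth.planted_pathway_ids) >= 0.8
        assert all(sn.s_a >= 3.0 for sn in subnets)

    def test_missing_significance_defaults_to_one(self, default_bundle):
        pnet = build_pathway_network(default_bundle.collection)
        # only the disease pathway has evidence; everything else p=1 by default
        truth = default_bundle.truth
        subnets = pathway_subnetworks(
            pnet, PathwaySignificance(entries={truth.disease_pathway_id: 1e-10}),
            cutoff=3.0, seed=2)
        for sn in subnets:
            assert truth.disease_pathway_id in sn.node_ids
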