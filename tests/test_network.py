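"""Graph centralities, modularity, community detection, bipartition scans."""

import math

import networkx as nx
import numpy as np
import pytest

from indivevol.network import (
    EXACT_MAX_NODES,
    InteractionGraph,
    Partition,
    bipartition_scan,
    centrality_rate_tests,
    closeness_centrality,
    communities,
    corrected_importance,
    eigen_centrality,
    exact_modularity_partition,
    importance_vector,
    modularity,
    module_rate_test,
    read_edge_list,
)
from indivevol.stats import mann_whitney
from indivevol.synthetic import paper_scale_network, simulate_network


def enumerate_partitions(nodes):
    """All set partitions of a node list (Bell-number many)."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for p in enumerate_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1 :]
        yield [[first]] + p


def as_partition(blocks):
    return Partition({n: i for i, blk in enumerate(blocks) for n in blk}, "enum")


class TestGraphType:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            InteractionGraph([("a", "a")])

    def test_total_interactions_below_degree_rejected(self):
        g = InteractionGraph([("a", "b"), ("a", "c")])
        with pytest.raises(ValueError):
            g.set_total_interactions("a", 1)

    def test_edge_list_round_trip(self, tmp_path):
        edges = tmp_path / "e.tsv"
        edges.write_text("node_a\tnode_b\ttype\nA\tB\tphysical\nB\tC\tgenetic\n")
        attrs = tmp_path / "a.tsv"
        attrs.write_text("gene\ttotal_interactions\trate\nA\t10\t0.001\nB\t5\t-\n")
        g = read_edge_list(edges, attrs)
        assert g.n_nodes == 3 and g.n_edges == 2
        assert g.total_interactions == {"A": 10, "B": 5}
        assert g.rates == {"A": 0.001}
        assert len(g.annotations) == 1 and g.annotations[0]["source"] == "B"


class TestCentrality:
    def test_closeness_path(self):
        g = InteractionGraph([("a", "b"), ("b", "c")])
        c = closeness_centrality(g)
        assert c["b"] == pytest.approx(1.0)
        assert c["a"] == pytest.approx(2 / 3)

    def test_closeness_star_and_complete(self):
        star = InteractionGraph([("c", f"l{i}") for i in range(3)])
        c = closeness_centrality(star)
        assert c["c"] == pytest.approx(1.0)
        assert c["l0"] == pytest.approx(0.6)
        k4 = InteractionGraph([(a, b) for a in "abcd" for b in "abcd" if a < b])
        assert all(v == pytest.approx(1.0) for v in closeness_centrality(k4).values())

    def test_closeness_disconnected_rejected(self):
        g = InteractionGraph([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="connected"):
            closeness_centrality(g)

    def test_eigen_path(self):
        g = InteractionGraph([("a", "b"), ("b", "c")])
        e = eigen_centrality(g)
        assert e["b"] == pytest.approx(1.0)
        assert e["a"] == pytest.approx(math.sqrt(2) / 2, abs=1e-6)

    def test_eigen_star_and_complete(self):
        star = InteractionGraph([("c", f"l{i}") for i in range(4)])
        e = eigen_centrality(star)
        assert e["c"] == pytest.approx(1.0)
        assert e["l0"] == pytest.approx(0.5, abs=1e-6)
        k3 = InteractionGraph([("a", "b"), ("b", "c"), ("a", "c")])
        assert all(v == pytest.approx(1.0) for v in eigen_centrality(k3).values())

    def test_eigen_matches_networkx(self):
        g, _ = simulate_network(seed=6)
        mine = eigen_centrality(g)
        ref = nx.eigenvector_centrality_numpy(g.graph)
        top = max(ref.values())
        for node in g.nodes:
            assert mine[node] == pytest.approx(ref[node] / top, abs=1e-6)

    def test_invariant_under_relabeling(self):
        g1 = InteractionGraph([("a", "b"), ("b", "c"), ("c", "d"), ("b", "d")])
        relabel = {"a": "w", "b": "x", "c": "y", "d": "z"}
        g2 = InteractionGraph([(relabel[u], relabel[v]) for u, v in g1.graph.edges])
        c1, c2 = closeness_centrality(g1), closeness_centrality(g2)
        for old, new in relabel.items():
            assert c1[old] == pytest.approx(c2[new])


class TestCorrectedImportance:
    @pytest.mark.parametrize(
        "cent, k, expected",
        [(1.0, 10, 1.0), (0.5, 2, 0.0), (0.6, 165, math.log10(99.0))],
    )
    def test_values(self, cent, k, expected):
        assert corrected_importance(cent, k) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            corrected_importance(0.0, 10)
        with pytest.raises(ValueError):
            corrected_importance(0.5, 0)


class TestModularity:
    def test_single_community_zero(self, two_triangles):
        g, _ = two_triangles
        assert modularity(g, Partition({n: 0 for n in g.nodes})) == 0.0

    def test_two_triangles_bridge_split(self, two_triangles):
        g, p = two_triangles
        assert modularity(g, p) == pytest.approx(6 / 7 - 0.5)

    def test_singletons_negative(self, two_triangles):
        g, _ = two_triangles
        p = Partition({n: i for i, n in enumerate(g.nodes)})
        m = g.n_edges
        expected = -sum((g.graph.degree(v) / (2 * m)) ** 2 for v in g.nodes)
        assert modularity(g, p) == pytest.approx(expected)
        assert modularity(g, p) < 0

    def test_matches_networkx(self):
        g, truth = simulate_network(seed=17)
        blocks = {}
        for node, c in truth["partition"].items():
            blocks.setdefault(c, set()).add(node)
        p = Partition(truth["partition"])
        assert modularity(g, p) == pytest.approx(
            nx.community.modularity(g.graph, list(blocks.values()))
        )


class TestCommunities:
    @pytest.mark.parametrize("method", ["fast_greedy", "louvain", "exact", "edge_betweenness"])
    def test_two_triangles_unique_optimum(self, two_triangles, method):
        g, planted = two_triangles
        p = communities(g, method=method, seed=1)
        assert set(p.communities_as_sets()) == set(planted.communities_as_sets())

    @pytest.mark.parametrize("method", ["fast_greedy", "exact"])
    def test_complete_graph_single_community(self, method):
        k5 = InteractionGraph([(a, b) for a in "abcde" for b in "abcde" if a < b])
        assert communities(k5, method=method).n_communities == 1

    def test_exact_refuses_oversized(self):
        g, _ = simulate_network(community_sizes=(8, 8), seed=1)
        assert g.n_nodes > EXACT_MAX_NODES
        with pytest.raises(ValueError, match="exact"):
            communities(g, method="exact")

    @pytest.mark.parametrize("method", ["louvain", "fast_greedy"])
    def test_planted_partition_recovered(self, method):
        g, truth = simulate_network(
            community_sizes=(8, 8), p_in=0.9, p_out=0.05, seed=13
        )
        p = communities(g, method=method, seed=13)
        planted = {}
        for node, c in truth["partition"].items():
            planted.setdefault(c, set()).add(node)
        assert set(p.communities_as_sets()) == {frozenset(s) for s in planted.values()}

    def test_exact_beats_every_enumerated_partition(self):
        rng = np.random.default_rng(0)
        checked = 0
        for seed in range(12):
            G = nx.gnp_random_graph(6, 0.5, seed=seed)
            if not nx.is_connected(G):
                continue
            ig = InteractionGraph([(str(u), str(v)) for u, v in G.edges])
            best_enum = max(
                modularity(ig, as_partition(p)) for p in enumerate_partitions(ig.nodes)
            )
            q_exact = modularity(ig, exact_modularity_partition(ig))
            q_greedy = modularity(ig, communities(ig, "fast_greedy"))
            assert q_exact == pytest.approx(best_enum, abs=1e-12)
            assert q_exact >= q_greedy - 1e-12
            checked += 1
        assert checked >= 5

    def test_better_than_singletons_on_planted_structure(self):
        g, _ = simulate_network(community_sizes=(6, 6), p_in=0.9, p_out=0.05, seed=5)
        singles = Partition({n: i for i, n in enumerate(g.nodes)})
        for method in ("fast_greedy", "louvain", "edge_betweenness"):
            p = communities(g, method, seed=5)
            assert modularity(g, p) > modularity(g, singles)
            assert modularity(g, p) > 0


class TestBipartitionScan:
    def test_single_bridge_complete_separation(self, two_triangles):
        g, p = two_triangles
        rates = {"a": 1, "b": 2, "c": 3, "d": 10, "e": 11, "f": 12}
        out = bipartition_scan(g, p, rates)
        assert len(out) == 1
        assert out[0].result.statistics["U_min"] == 0.0
        assert set(out[0].side_a) | set(out[0].side_b) == set(g.nodes)

    def test_parallel_intercommunity_edges_do_not_qualify(self):
        g = InteractionGraph(
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("d", "e"), ("e", "f"), ("d", "f"),
             ("c", "d"), ("a", "f")]
        )
        p = Partition({"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1})
        assert bipartition_scan(g, p, {n: 1.0 + i for i, n in enumerate(g.nodes)}) == []

    def test_chain_of_three_communities_two_cuts(self):
        g, truth = simulate_network(
            community_sizes=(5, 5, 5),
            p_in=1.0,
            p_out=0.0,
            seed=21,
            rate_shifts=(1.0, 2.0, 4.0),
            require_connected=False,
        )
        # wire the cliques into a chain with single bridges
        g.graph.add_edge("n00", "n05")
        g.graph.add_edge("n09", "n10")
        p = Partition(truth["partition"])
        out = bipartition_scan(g, p)
        assert len(out) == 2
        for rec in out:
            direct = mann_whitney(
                [g.rates[n] for n in rec.side_a], [g.rates[n] for n in rec.side_b]
            )
            assert rec.result.p_value == direct.p_value
            assert rec.result.statistics == direct.statistics

    def test_sides_partition_nodes(self, two_triangles):
        g, p = two_triangles
        out = bipartition_scan(g, p, {n: float(i + 1) for i, n in enumerate(g.nodes)})
        sides = set(out[0].side_a) | set(out[0].side_b)
        assert sides == set(g.nodes)
        assert not (set(out[0].side_a) & set(out[0].side_b))


class TestCentralityRateTests:
    def test_rates_equal_closeness_perfect_rho(self):
        g, _ = simulate_network(seed=3)
        c = closeness_centrality(g)
        res = centrality_rate_tests(g, rates=c, measure="closeness")
        assert res.statistics["rho"] == pytest.approx(1.0)

    def test_s_rho_identity_at_study_sizes(self):
        for n_extra, n_expected in ((0, 21), (2, 19)):
            g, _ = simulate_network(seed=4)
            rates = dict(g.rates)
            for node in g.nodes[:n_extra]:
                del rates[node]
            res = centrality_rate_tests(g, rates=rates, measure="eigen")
            assert res.n_per_group == (n_expected,)
            n = n_expected
            S, rho = res.statistics["S"], res.statistics["rho"]
            assert rho == pytest.approx(1 - 6 * S / (n**3 - n), abs=1e-9)

    def test_too_few_pairs_rejected(self):
        g = InteractionGraph([("a", "b"), ("b", "c")])
        with pytest.raises(ValueError):
            centrality_rate_tests(g, rates={"a": 1.0, "b": 2.0})


class TestModuleRateTest:
    def test_matches_direct_kruskal(self):
        g, truth = simulate_network(seed=8, rate_shifts=(1, 2, 4, 1, 2))
        p = Partition(truth["partition"])
        res = module_rate_test(g, p)
        assert res.method == "kruskal_wallis"
        assert res.p_value <= 1.0


class TestPaperScaleSurrogate:
    def test_size_and_connectivity(self):
        g, truth = paper_scale_network(seed=0)
        assert g.n_nodes == 21 and g.n_edges == 28
        assert g.is_connected()
        assert "synthetic" in truth["surrogate"]
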