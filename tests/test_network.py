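import networkx as nx
import numpy as np
import pytest

from planktonscape.data_io import OTUTable
from planktonscape.network import (
    build_network,
    correlation_edges,
    detect_modules,
    filter_otus_for_network,
    key_species,
    topology_metrics,
    zi_pi,
)

from .oracles import (
    brute_average_degree,
    brute_clustering,
    brute_density,
    brute_diameter_apl,
    brute_modularity,
    brute_zi_pi,
    random_graph,
)


def _table(counts):
    counts = np.asarray(counts)
    return OTUTable(
        [f"o{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
        counts,
    )


class TestFilter:
    def test_zero_thresholds_identity(self, rng):
        t = _table(rng.integers(0, 10, (20, 9)) + (rng.random((20, 9)) < 0.2))
        out = filter_otus_for_network(t, 0.0, 0.0)
        assert out.otu_ids == t.otu_ids

    def test_rare_otu_removed(self):
        counts = np.ones((3, 9), dtype=int) * 5
        counts[2] = 0
        counts[2, 0] = 1  # present in 1 of 9 samples
        out = filter_otus_for_network(_table(counts), min_prevalence=1 / 3,
                                      min_mean_abund=0.0)
        assert "o2" not in out.otu_ids

    def test_survivors_match_brute_force(self, rng):
        counts = rng.integers(0, 6, (40, 12))
        counts[:, 0] += 1
        t = _table(counts)
        min_prev, min_abund = 0.4, 0.01
        out = filter_otus_for_network(t, min_prev, min_abund)
        rel = counts / counts.sum(axis=0)
        expected = [
            t.otu_ids[i]
            for i in range(40)
            if (counts[i] > 0).mean() >= min_prev and rel[i].mean() >= min_abund
        ]
        assert out.otu_ids == expected

    def test_empty_result_advises(self):
        counts = np.zeros((4, 8), dtype=int)
        for i in range(4):
            counts[i, 2 * i: 2 * i + 2] = 3  # every sample covered, all OTUs sparse
        with pytest.raises(ValueError, match="min_prevalence"):
            filter_otus_for_network(_table(counts), 0.99, 0.99)


class TestCorrelationEdges:
    def test_perfect_pair_retained(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8])
        t = _table(np.vstack([x, 2 * x, 9 - x]))
        edges = correlation_edges(t, min_abs_r=0.9, alpha=0.05)
        pairs = {frozenset((a, b)) for a, b in zip(edges.otu_a, edges.otu_b)}
        assert frozenset(("o0", "o1")) in pairs
        pos = edges[(edges.otu_a == "o0") & (edges.otu_b == "o1")]
        assert pos["sign"].iloc[0] == "positive"
        assert pos["rho"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelated_pair_negative_sign(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8])
        t = _table(np.vstack([x, 9 - x]))
        edges = correlation_edges(t, min_abs_r=0.9)
        assert edges["sign"].iloc[0] == "negative"

    def test_constant_otu_skipped_with_warning(self):
        # o1 holds exactly half of every library, so its relative abundance
        # is constant and it cannot enter a rank correlation
        x = np.array([1, 2, 3, 4, 5, 6])
        t = _table(np.vstack([x, np.full(6, 7), x[::-1]]))  # o1 = half of each total
        assert np.allclose(t.relative_abundance()[1], 0.5)
        with pytest.warns(UserWarning, match="o1"):
            correlation_edges(t, min_abs_r=0.0, alpha=1.0)

    def test_null_fdr_controlled(self, rng):
        # independent OTUs: after BH, the fraction of tested pairs that
        # survive stays at or below alpha
        counts = rng.integers(1, 100, size=(40, 30))
        t = _table(counts)
        edges = correlation_edges(t, min_abs_r=0.0, alpha=0.05)
        n_pairs = 40 * 39 / 2
        assert len(edges) / n_pairs <= 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="5 samples"):
            correlation_edges(_table(np.ones((3, 4), dtype=int)))


class TestTopology:
    def test_complete_graph_k4(self):
        g = nx.complete_graph(4)
        topo = topology_metrics(g)
        assert topo.density == pytest.approx(1.0)
        assert topo.average_clustering == pytest.approx(1.0)
        assert topo.diameter == 1
        assert topo.average_path_length == pytest.approx(1.0)

    def test_path_graph_hand_enumeration(self):
        g = nx.path_graph(3)
        topo = topology_metrics(g)
        assert topo.average_degree == pytest.approx(4 / 3)
        assert topo.diameter == 2
        assert topo.average_path_length == pytest.approx((1 + 1 + 2) / 3)

    def test_two_cliques_modularity_via_explicit_q(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        partition = {i: 0 if i < 4 else 1 for i in g.nodes()}
        topo = topology_metrics(g, partition)
        q = brute_modularity(list(g.nodes()), list(g.edges()), partition)
        assert topo.modularity == pytest.approx(q, abs=1e-12)
        assert topo.modularity == pytest.approx(0.5)

    def test_edgeless_graph_reports_na_paths(self):
        g = nx.empty_graph(3)
        topo = topology_metrics(g)
        assert topo.n_edges == 0
        assert topo.diameter is None and topo.average_path_length is None

    def test_percentages_sum_to_100(self):
        g = nx.Graph()
        g.add_edge("a", "b", sign="positive")
        g.add_edge("b", "c", sign="negative")
        topo = topology_metrics(g)
        assert topo.pct_positive + topo.pct_negative == pytest.approx(100.0)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(8):
            nodes, edges, partition = random_graph(rng, max_nodes=25)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            if not edges:
                continue
            topo = topology_metrics(g, partition)
            assert topo.density == pytest.approx(brute_density(nodes, edges))
            assert topo.average_degree == pytest.approx(brute_average_degree(nodes, edges))
            assert topo.average_clustering == pytest.approx(
                brute_clustering(nodes, edges), abs=1e-12
            )
            diam, apl = brute_diameter_apl(nodes, edges)
            assert topo.diameter == pytest.approx(diam)
            assert topo.average_path_length == pytest.approx(apl, abs=1e-12)
            assert topo.modularity == pytest.approx(
                brute_modularity(nodes, edges, partition), abs=1e-12
            )


class TestModules:
    def test_two_cliques_recovered(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        part = detect_modules(g, seed=0)
        mods_left = {part[i] for i in range(5)}
        mods_right = {part[i] for i in range(5, 10)}
        assert len(mods_left) == 1 and len(mods_right) == 1
        assert mods_left != mods_right

    def test_complete_graph_single_module(self):
        part = detect_modules(nx.complete_graph(6), seed=0)
        assert len(set(part.values())) == 1

    def test_q_at_least_trivial_partition(self, rng):
        nodes, edges, _ = random_graph(rng, max_nodes=30)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if g.number_of_edges() == 0:
            return
        part = detect_modules(g, seed=1)
        q = brute_modularity(nodes, list(g.edges()), part)
        assert q >= -1e-12


class TestZiPi:
    def test_all_internal_edges_give_zero_pi(self):
        g = nx.complete_graph(4)
        part = {v: 0 for v in g.nodes()}
        roles = zi_pi(g, part)
        assert all(r.pi == 0.0 for r in roles)

    def test_even_split_over_two_modules(self):
        g = nx.star_graph(4)  # hub 0 with leaves 1-4
        part = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1}
        roles = {r.otu_id: r for r in zi_pi(g, part)}
        assert roles[0].pi == pytest.approx(1 - 2 * 0.25)

    def test_role_quadrants_consistent_with_thresholds(self, rng):
        # on random graphs every assigned role must match the (2.5, 0.62)
        # quadrant of the node's own (Zi, Pi) pair
        for _ in range(5):
            nodes, edges, partition = random_graph(rng, max_nodes=30)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            for r in zi_pi(g, partition):
                hub, conn = r.zi > 2.5, r.pi > 0.62
                expected = ("network hub" if hub and conn else "module hub" if hub
                            else "connector" if conn else "peripheral")
                assert r.role == expected

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(8):
            nodes, edges, partition = random_graph(rng, max_nodes=25)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            expected = brute_zi_pi(nodes, edges, partition)
            for r in zi_pi(g, partition):
                zi, pi = expected[r.otu_id]
                assert r.zi == pytest.approx(zi, abs=1e-12)
                assert r.pi == pytest.approx(pi, abs=1e-12)
                assert 0 <= r.pi < 1

    def test_isolated_node_is_peripheral(self):
        g = nx.Graph()
        g.add_node("lonely")
        roles = zi_pi(g, {"lonely": 0})
        assert roles[0].role == "peripheral"
        assert roles[0].zi == 0.0 and roles[0].pi == 0.0

    def test_partition_must_cover(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError, match="cover"):
            zi_pi(g, {0: 0, 1: 0})


class TestKeySpecies:
    def test_all_peripheral_gives_empty(self):
        g = nx.complete_graph(4)
        roles = zi_pi(g, {v: 0 for v in g.nodes()})
        assert len(key_species(roles)) == 0

    def test_planted_connector_found(self):
        # three triangles bridged by one node spreading its edges evenly
        # across the three modules: Pi = 1 - 3*(1/3)^2 = 2/3 > 0.62
        g = nx.Graph()
        for tri, mod in ((("a", "b", "c"), 0), (("d", "e", "f"), 1), (("g", "h", "i"), 2)):
            g.add_edges_from([(tri[0], tri[1]), (tri[1], tri[2]), (tri[0], tri[2])])
        g.add_edges_from([("x", "a"), ("x", "d"), ("x", "g")])
        part = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1,
                "g": 2, "h": 2, "i": 2, "x": 0}
        roles = zi_pi(g, part)
        keys = key_species(roles)
        assert list(keys["otu_id"]) == ["x"]
        assert keys["role"].iloc[0] == "connector"

    def test_size_matches_non_peripheral_count(self, rng):
        nodes, edges, partition = random_graph(rng)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        roles = zi_pi(g, partition)
        keys = key_species(roles)
        assert len(keys) == sum(r.role != "peripheral" for r in roles)


class TestBuildNetwork:
    def test_nodes_and_attributes(self):
        x = np.arange(1, 9)
        t = _table(np.vstack([x, 2 * x, 9 - x, x * 0 + 3]))
        edges = correlation_edges(t, min_abs_r=0.9)
        g = build_network(t, edges)
        assert set(g.nodes()) <= set(t.otu_ids)
        for _, _, d in g.edges(data=True):
            assert d["sign"] in ("positive", "negative")
            assert abs(d["rho"]) >= 0.9
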