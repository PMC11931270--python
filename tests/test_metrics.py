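"""Centralities, hubs, and global metrics against brute-force oracles."""

import numpy as np
import pytest

import fosnet as f
from conftest import net_from_edges, random_weighted_net
from oracles import (brute_betweenness, brute_global_efficiency,
                     brute_strength, brute_transitivity)


def _by_region(metrics):
    return {m.region: m for m in metrics}


class TestNodeCentralities:
    def test_path_graph_betweenness(self):
        net = net_from_edges("ABC", {("A", "B"): 1.0, ("B", "C"): 1.0})
        m = _by_region(f.node_centralities(net))
        assert m["B"].betweenness == pytest.approx(1.0)
        assert m["A"].betweenness == 0.0
        assert m["B"].degree == 2 and m["A"].degree == 1

    def test_star_graph(self):
        leaves = ["L1", "L2", "L3", "L4"]
        net = net_from_edges(["X"] + leaves,
                             {("X", leaf): 1.0 for leaf in leaves})
        m = _by_region(f.node_centralities(net))
        assert m["X"].betweenness == pytest.approx(6.0)  # C(4,2)
        assert m["X"].degree == 4
        assert f.identify_hubs(f.node_centralities(net)) == {"X"}

    def test_strength_is_sum_of_absolute_rho(self):
        net = net_from_edges("ABC", {("A", "B"): 0.9, ("A", "C"): -0.4})
        m = _by_region(f.node_centralities(net))
        assert m["A"].strength == pytest.approx(1.3)
        assert m["A"].degree == 2

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        unit = bool(rng.random() < 0.5)
        net, nodes, lengths, weights = random_weighted_net(rng, n, unit=unit)
        m = _by_region(f.node_centralities(net))
        btw = brute_betweenness(lengths, nodes)
        s = brute_strength(lengths, nodes)
        for v in nodes:
            assert m[v].betweenness == pytest.approx(btw[v], abs=1e-10)
            assert m[v].strength == pytest.approx(s[v], abs=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        net, nodes, lengths, weights = random_weighted_net(rng, 6)
        perm = list(np.random.default_rng(1).permutation(nodes))
        mapping = dict(zip(nodes, perm))
        edges2 = {(mapping[u], mapping[v]): 1.0 / L
                  for (u, v), L in ((tuple(k), v) for k, v in lengths.items())}
        net2 = net_from_edges(perm, edges2)
        m1 = _by_region(f.node_centralities(net))
        m2 = _by_region(f.node_centralities(net2))
        for v in nodes:
            assert m1[v].degree == m2[mapping[v]].degree
            assert m1[v].strength == pytest.approx(m2[mapping[v]].strength)
            assert m1[v].betweenness == pytest.approx(
                m2[mapping[v]].betweenness)


class TestGlobalMetrics:
    def test_triangle(self):
        net = net_from_edges("ABC", {("A", "B"): 1.0, ("B", "C"): 1.0,
                                     ("A", "C"): 1.0})
        g = f.global_metrics(net)
        assert g.transitivity == pytest.approx(1.0)
        assert g.global_efficiency == pytest.approx(1.0)

    def test_single_edge_three_nodes(self):
        net = net_from_edges("ABC", {("A", "B"): 1.0})
        g = f.global_metrics(net)
        assert g.transitivity == 0.0  # no connected triples
        assert g.global_efficiency == pytest.approx(1 / 3)

    def test_k4_minus_edge_matches_oracle(self):
        edges = {("A", "B"): 1.0, ("A", "C"): 1.0, ("A", "D"): 1.0,
                 ("B", "C"): 1.0, ("B", "D"): 1.0}
        net = net_from_edges("ABCD", edges)
        g = f.global_metrics(net)
        lengths = {frozenset(k): 1.0 for k in edges}
        assert g.transitivity == pytest.approx(
            brute_transitivity(lengths, list("ABCD")))
        assert g.global_efficiency == pytest.approx(
            brute_global_efficiency(lengths, list("ABCD")))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_on_random_graphs(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(2, 7))
        net, nodes, lengths, _ = random_weighted_net(rng, n)
        g = f.global_metrics(net)
        assert g.transitivity == pytest.approx(
            brute_transitivity(lengths, nodes), abs=1e-10)
        assert g.global_efficiency == pytest.approx(
            brute_global_efficiency(lengths, nodes), abs=1e-10)

    def test_adding_edge_never_decreases_efficiency(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            net, nodes, lengths, weights = random_weighted_net(rng, 6)
            missing = [(a, b) for i, a in enumerate(nodes)
                       for b in nodes[i + 1:]
                       if frozenset({a, b}) not in lengths]
            if not missing:
                continue
            extra = missing[int(rng.integers(len(missing)))]
            w = float(rng.uniform(0.2, 1.0))
            edges2 = {}
            for k, L in lengths.items():
                u, v = tuple(k)
                edges2[(u, v)] = 1.0 / L
            before = f.global_metrics(net).global_efficiency
            edges2[extra] = w
            after = f.global_metrics(
                net_from_edges(nodes, edges2)).global_efficiency
            assert after >= before - 1e-12

    def test_onnela_variant_available(self):
        net = net_from_edges("ABC", {("A", "B"): 0.9, ("B", "C"): 0.5,
                                     ("A", "C"): 0.7})
        g = f.global_metrics(net, transitivity_variant="onnela")
        assert 0.0 < g.transitivity <= 1.0


class TestHubs:
    def test_two_disconnected_triangles_no_hub(self):
        edges = {("A", "B"): 0.8, ("B", "C"): 0.8, ("A", "C"): 0.8,
                 ("D", "E"): 0.8, ("E", "F"): 0.8, ("D", "F"): 0.8}
        net = net_from_edges("ABCDEF", edges)
        assert f.identify_hubs(f.node_centralities(net)) == set()

    def test_bridge_structure_dominates_centralities_at_large_n(
            self, li_config):
        """In the two-block regime all cross-block shortest paths funnel
        through the DG-DLENT bridge, so those two nodes own the top
        betweenness ranks and DG (bridge + largest block) is always a hub;
        perirhinal nodes never are."""
        t = f.generate_condition_counts(li_config, "LI", n_subjects=2000)
        net = f.build_network(t)
        metrics = f.node_centralities(net)
        by_region = _by_region(metrics)
        top_btw = {m.region for m in metrics if m.rank_betweenness <= 2}
        assert top_btw == {"DG", "DLENT"}
        hubs = f.identify_hubs(metrics)
        assert "DG" in hubs
        assert not hubs & {"PRH35", "PRH36"}
        assert by_region["DG"].rank_strength == 1.0

    def test_too_few_nodes_rejected(self):
        net = net_from_edges("AB", {("A", "B"): 0.5})
        with pytest.raises(ValueError, match="at least 3"):
            f.identify_hubs(f.node_centralities(net))
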