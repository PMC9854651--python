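"""Induced PPI subnetworks, connectivity, greedy expansion, edge categories."""

import networkx as nx
import pytest

from pigmentnet.errors import ConfigurationError
from pigmentnet.io import (
    NetworkClass,
    PPINetwork,
    ScoredEdge,
    ScoredEdgeTable,
)
from pigmentnet.ppi import (
    categorize_edges,
    connectivity_summary,
    expand_network,
    induced_subnetwork,
    round_half_up,
)


def table(*triples):
    return ScoredEdgeTable.from_edges([ScoredEdge(a, b, s) for a, b, s in triples])


class TestInducedSubnetwork:
    def test_threshold_is_inclusive(self):
        net = induced_subnetwork(table(("A", "B", 0.700), ("A", "C", 0.699)),
                                 ["A", "B", "C"], 0.700)
        assert net.edge_set() == {("A", "B", 0.700)}
        assert net.unconnected_seeds == {"C"}

    def test_non_seed_endpoints_excluded(self):
        net = induced_subnetwork(table(("A", "X", 0.9)), ["A", "B"], 0.700)
        assert net.n_nodes == 0 and net.unconnected_seeds == {"A", "B"}

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            induced_subnetwork(table(("A", "B", 0.9)), ["A", "B"], 1.5)

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ConfigurationError):
            induced_subnetwork(table(("A", "B", 0.9)), [], 0.7)

    def test_filtering_is_monotone_in_threshold(self, sim_dir, curated_table):
        from pigmentnet.io import read_scored_edges
        edges = read_scored_edges(sim_dir.ppi_edges)
        seeds = sorted(curated_table.genes)
        prev_nodes, prev_edges = None, None
        for thr in (0.4, 0.6, 0.700, 0.8, 0.95):
            net = induced_subnetwork(edges, seeds, thr)
            if prev_nodes is not None:
                assert net.n_nodes <= prev_nodes and net.n_edges <= prev_edges
            prev_nodes, prev_edges = net.n_nodes, net.n_edges


class TestConnectivity:
    def test_rounding_reproduces_integer_percent(self):
        # 169 connected of 243 seeds is 69.5..., reported as 70%
        g = nx.complete_graph(range(169))
        g = nx.relabel_nodes(g, {i: f"P{i}" for i in range(169)})
        nx.set_edge_attributes(g, 0.9, "score")
        net = PPINetwork(graph=g)
        seeds = [f"P{i}" for i in range(243)]
        assert connectivity_summary(net, seeds).connected_fraction == 70

    def test_all_isolated_is_zero_percent(self):
        net = induced_subnetwork(table(("A", "B", 0.1)), ["A", "B"], 0.7)
        assert connectivity_summary(net, ["A", "B"]).connected_fraction == 0

    def test_complete_graph_is_one_component_at_100(self):
        net = induced_subnetwork(
            table(("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.9)),
            ["A", "B", "C"], 0.7)
        s = connectivity_summary(net, ["A", "B", "C"])
        assert s.connected_fraction == 100 and s.component_sizes == (3,)

    def test_round_half_up_behaviour(self):
        assert round_half_up(69.5) == 70
        assert round_half_up(69.49) == 69


class TestExpansion:
    def test_greedy_prefers_highest_summed_score(self):
        seed = induced_subnetwork(table(("A", "B", 0.9)), ["A", "B"], 0.7)
        background = table(("A", "B", 0.9), ("A", "X", 0.9), ("B", "X", 0.9),
                           ("A", "Y", 0.8))
        out = expand_network(seed, background, 0.7, edge_target=2)
        # X (summed 1.8) is added before Y (0.8); 3 edges > 2 stops there
        assert set(out.graph.nodes) == {"A", "B", "X"}
        assert out.graph.nodes["X"]["provenance"] == "ADDED"
        assert out.graph.nodes["X"]["network_class"] == "NONE"

    def test_already_above_target_returns_unchanged(self):
        edges = table(("A", "B", 0.9), ("B", "C", 0.9), ("C", "D", 0.9),
                      ("D", "E", 0.9), ("E", "A", 0.9))
        seed = induced_subnetwork(edges, list("ABCDE"), 0.7)
        out = expand_network(seed, table(("A", "X", 0.99)), 0.7, edge_target=0)
        assert set(out.graph.nodes) == set("ABCDE") and out.n_edges == 5

    def test_background_exhaustion_returns_maximal_network(self, caplog):
        seed = induced_subnetwork(table(("A", "B", 0.9)), ["A", "B"], 0.7)
        out = expand_network(seed, table(("A", "X", 0.9)), 0.7, edge_target=100)
        assert set(out.graph.nodes) == {"A", "B", "X"} and out.n_edges == 2

    def test_tie_broken_by_edge_count_then_symbol(self):
        seed = induced_subnetwork(table(("A", "B", 0.9)), ["A", "B"], 0.7)
        # X: one 0.9 edge; W: two 0.45-sum... make sums equal: W has 2 edges summing 0.9
        background = table(("A", "B", 0.9), ("A", "X", 0.9),
                           ("A", "W", 0.45), ("B", "W", 0.45))
        out = expand_network(seed, background, 0.0, edge_target=2)
        assert "W" in out.graph.nodes and "X" not in out.graph.nodes

    def test_expansion_matches_brute_force_candidate_reranking(self, spec):
        """On a synthetic background (<=200 proteins) the greedy member
        sequence equals exhaustive re-scoring of every candidate at every
        step."""
        from pigmentnet.io import read_scored_edges
        from pigmentnet.simulate import gen_ppi
        edges, truth = gen_ppi(spec)
        members0 = sorted({g for mod in truth.modules for g in mod})
        seed = induced_subnetwork(edges, members0, 0.700)
        target = seed.n_edges + 120
        out = expand_network(seed, edges, 0.700, edge_target=target)
        assert len(edges.proteins) <= 200

        # independent oracle: re-rank all candidates from scratch each step
        filt = [e for e in edges.edges if e.score >= 0.700]
        members = set(seed.graph.nodes)
        g = nx.Graph()
        g.add_nodes_from(members)
        for e in filt:
            if e.protein_a in members and e.protein_b in members:
                g.add_edge(e.protein_a, e.protein_b)
        order = []
        while g.number_of_edges() <= target:
            scores = {}
            for e in filt:
                for cand, other in ((e.protein_a, e.protein_b),
                                    (e.protein_b, e.protein_a)):
                    if cand not in members and other in members:
                        tot, cnt = scores.get(cand, (0.0, 0))
                        scores[cand] = (tot + e.score, cnt + 1)
            if not scores:
                break
            pick = min(scores, key=lambda c: (-scores[c][0], -scores[c][1], c))
            order.append(pick)
            members.add(pick)
            for e in filt:
                if e.protein_a in members and e.protein_b in members:
                    g.add_edge(e.protein_a, e.protein_b)
        expected_added = set(order)
        got_added = {n for n, d in out.graph.nodes(data=True)
                     if d["provenance"] == "ADDED"}
        assert got_added == expected_added
        assert out.n_edges == g.number_of_edges()

    def test_expansion_is_deterministic(self, spec):
        from pigmentnet.simulate import gen_ppi
        edges, truth = gen_ppi(spec)
        members0 = sorted({g for mod in truth.modules for g in mod})
        seed = induced_subnetwork(edges, members0, 0.700)
        runs = [expand_network(seed, edges, 0.700, edge_target=seed.n_edges + 80)
                for _ in range(2)]
        assert sorted(runs[0].graph.nodes) == sorted(runs[1].graph.nodes)
        assert runs[0].edge_set() == runs[1].edge_set()

    def test_induced_subnetwork_of_expansion_reproduces_seed(self, spec):
        from pigmentnet.simulate import gen_ppi
        edges, truth = gen_ppi(spec)
        members0 = sorted({g for mod in truth.modules for g in mod})
        seed = induced_subnetwork(edges, members0, 0.700)
        out = expand_network(seed, edges, 0.700, edge_target=seed.n_edges + 60)
        back = out.graph.subgraph(
            n for n, d in out.graph.nodes(data=True) if d["provenance"] == "SEED")
        assert {frozenset(e) for e in back.edges} == {
            frozenset(e) for e in seed.graph.edges}


class TestEdgeCategories:
    def _net(self, classes, edges):
        g = nx.Graph()
        for n, c in classes.items():
            g.add_node(n, network_class=c)
        for a, b in edges:
            g.add_edge(a, b, score=0.9)
        return PPINetwork(graph=g)

    def test_triangle_with_mixed_classes(self):
        net = self._net({"A": "HYPER", "B": "HYPER", "C": "HYPO"},
                        [("A", "B"), ("B", "C"), ("A", "C")])
        counts = {c.category_pair: c.count for c in categorize_edges(net)}
        assert counts == {("HYPER", "HYPER"): 1, ("HYPER", "HYPO"): 2}

    def test_single_class_collapses_to_one_category(self):
        net = self._net({"A": "NONE", "B": "NONE", "C": "NONE"},
                        [("A", "B"), ("B", "C")])
        counts = categorize_edges(net)
        assert len(counts) == 1 and counts[0].count == 2

    def test_category_counts_sum_to_edge_total(self, spec):
        from pigmentnet.simulate import gen_ppi
        edges, truth = gen_ppi(spec)
        members0 = sorted({g for mod in truth.modules for g in mod})
        classes = {g: NetworkClass.HYPER if i % 2 else NetworkClass.HYPO
                   for i, g in enumerate(members0)}
        seed = induced_subnetwork(edges, members0, 0.700, classes=classes)
        out = expand_network(seed, edges, 0.700, edge_target=seed.n_edges + 50,
                             classes=classes)
        cats = categorize_edges(out)
        assert sum(c.count for c in cats) == out.n_edges
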