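"""Interaction-network construction, topology summary, the twelve
centralities (with brute-force oracles) and hub frequency."""

import math

import networkx as nx
import numpy as np
import pytest

from stingnet import (
    Compartment,
    InteractionNetwork,
    METRICS,
    ReactionModel,
    Reaction,
    Species,
    centrality,
    centrality_table,
    hub_frequency,
    mass_action,
    model_to_network,
    random_graph,
    topology_summary,
)

from _oracles import (
    adjacency,
    betweenness_oracle,
    dmnc_oracle,
    mcc_oracle,
    mnc_oracle,
    stress_oracle,
)


def net_from_edges(edges):
    g = nx.Graph(edges)
    return InteractionNetwork.from_undirected(g)


def star(n_leaves=4):
    return net_from_edges([("hub", f"leaf{i}") for i in range(n_leaves)])


class TestModelToNetwork:
    def test_single_reaction_edges(self):
        model = ReactionModel(
            name="m",
            compartments=[Compartment("c", "c")],
            species=[Species(s, s, "c", 1.0) for s in "ABC"],
            reactions=[
                Reaction("r", "A+B->C", [("A", 1), ("B", 1)], [("C", 1)],
                         mass_action(1.0)),
            ],
        )
        net = model_to_network(model)
        assert set(net.graph.edges) == {("A", "C"), ("B", "C")}
        assert net.n_nodes == 3

    def test_curated_network_node_and_edge_counts(self, nsclc_network):
        assert nsclc_network.n_nodes == 89
        assert nsclc_network.undirected().number_of_edges() == 102

    def test_modifiers_are_sources(self, nsclc_model, nsclc_network):
        r = nsclc_model.get_reaction("r06")  # STING activation, cGAMP modifier
        assert ("cgamp_er", "cgsting_er") in nsclc_network.graph.edges


def test_edgelist_and_graphml_round_trip(nsclc_network, tmp_path):
    df = nsclc_network.to_edgelist()
    again = InteractionNetwork.from_edgelist(df)
    assert set(again.graph.edges) == set(nsclc_network.graph.edges)
    path = tmp_path / "net.graphml"
    nsclc_network.write_graphml(path)
    reread = nx.read_graphml(path)
    assert reread.number_of_nodes() == 89
    assert reread.number_of_edges() == nsclc_network.graph.number_of_edges()


class TestTopologySummary:
    def test_path_graph_radius_and_diameter(self):
        net = net_from_edges([("A", "B"), ("B", "C")])
        ts = topology_summary(net)
        assert (ts.radius, ts.diameter) == (1, 2)

    def test_triangle_clustering(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        assert topology_summary(net).avg_clustering == pytest.approx(1.0)

    def test_curated_radius_diameter_clustering(self, nsclc_network):
        ts = topology_summary(nsclc_network)
        assert ts.radius == 11
        assert ts.diameter == 19
        assert round(ts.avg_clustering, 3) == 0.034

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            topology_summary(InteractionNetwork(graph=nx.DiGraph()))


class TestCentralityBasics:
    def test_star_center_degree_and_betweenness(self):
        net = star(4)
        assert centrality(net, "degree")["hub"] == 4
        assert centrality(net, "betweenness")["hub"] == pytest.approx(6.0)

    def test_triangle_mcc_is_factorial_two(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        assert centrality(net, "MCC")["A"] == pytest.approx(2.0)

    @pytest.mark.parametrize("n", [4, 6])
    def test_complete_graph_invariants(self, n):
        net = InteractionNetwork.from_undirected(nx.complete_graph(n))
        assert all(v == 0 for v in centrality(net, "betweenness").values())
        assert all(v == 0 for v in centrality(net, "stress").values())
        assert all(
            v == pytest.approx(n - 1) for v in centrality(net, "closeness").values()
        )
        assert all(
            v == pytest.approx(math.factorial(n - 1))
            for v in centrality(net, "MCC").values()
        )

    def test_eccentricity_is_reciprocal_of_longest_shortest_path(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "D")])
        ecc = centrality(net, "eccentricity")
        assert ecc["A"] == pytest.approx(1 / 3)
        assert ecc["B"] == pytest.approx(1 / 2)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            centrality(star(), "pagerank")


class TestEPC:
    def test_requires_seed(self):
        with pytest.raises(ValueError):
            centrality(star(), "EPC")

    def test_keep_probability_one_gives_component_size(self):
        net = star(4)
        epc = centrality(net, "EPC", keep_probability=1.0, seed=0,
                         n_realizations=10)
        assert all(v == pytest.approx(5.0) for v in epc.values())

    def test_seeded_reproducibility(self):
        net = random_graph(12, 0.3, seed=5)
        a = centrality(net, "EPC", seed=42, n_realizations=50)
        b = centrality(net, "EPC", seed=42, n_realizations=50)
        assert a == b


class TestBottleneck:
    def test_star_center_dominates_every_tree(self):
        net = star(8)
        bn = centrality(net, "bottleneck")
        # center's subtree covers all nodes from every root
        assert bn["hub"] == 9.0

    def test_path_midpoint_scores_higher_than_leaf_neighbors(self):
        net = net_from_edges([(f"n{i}", f"n{i+1}") for i in range(6)])
        bn = centrality(net, "bottleneck")
        assert bn["n3"] >= bn["n1"]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
    def test_exact_match_on_seeded_random_graphs(self, seed):
        net = random_graph(10, 0.3, seed=seed)
        adj = adjacency(net.undirected())
        oracles = {
            "betweenness": betweenness_oracle,
            "stress": stress_oracle,
            "MCC": mcc_oracle,
            "MNC": mnc_oracle,
            "DMNC": dmnc_oracle,
        }
        for metric, oracle in oracles.items():
            ours = centrality(net, metric)
            ref = oracle(adj)
            for v in adj:
                assert ours[v] == pytest.approx(ref[v], abs=1e-9), (metric, v)

    def test_permutation_equivariance(self):
        net = random_graph(9, 0.35, seed=3)
        g = net.undirected()
        mapping = {v: f"z{v}" for v in g.nodes}
        relabeled = InteractionNetwork.from_undirected(nx.relabel_nodes(g, mapping))
        for metric in ("degree", "betweenness", "MCC", "radiality", "stress"):
            a = centrality(net, metric)
            b = centrality(relabeled, metric)
            for v in g.nodes:
                assert b[mapping[v]] == pytest.approx(a[v])


class TestHubFrequency:
    def test_single_metric_everyone_scores_one(self, nsclc_network):
        table = centrality_table(nsclc_network, seed=0, n_realizations=10)
        report = hub_frequency(table[["degree"]], k=len(table))
        assert set(report.frequency.values()) == {1}

    def test_top_node_in_every_metric_scores_twelve(self):
        net = star(6)
        table = centrality_table(net, seed=0, n_realizations=20)
        report = hub_frequency(table, k=1)
        assert report.frequency["hub"] == 12

    def test_invalid_k_rejected(self, nsclc_network):
        table = centrality_table(nsclc_network, seed=0, n_realizations=10)
        with pytest.raises(ValueError):
            hub_frequency(table, k=0)

    def test_curated_hubs_lead_with_phagophore_and_stat3_dimer(self, nsclc_network):
        """The phagophore tops the frequency-of-occurrence ranking and the
        STAT3 dimer sits in the leading hub tier."""
        table = centrality_table(nsclc_network, seed=1)
        report = hub_frequency(table, k=20)
        assert "phag" in report.max_frequency_nodes()
        ranked = [node for node, _ in report.ranked()]
        assert "stat3d" in ranked[:10]
        assert report.frequency["stat3d"] >= 9
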