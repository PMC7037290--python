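"""Induced PPI subnetworks, degree reports, hub and regulator selection."""

import numpy as np
import pytest

from diseasome_kit import (
    InteractionTable,
    generate_interaction_table,
    induce_ppi,
    node_degrees,
    regulator_network,
    select_hubs,
)
from oracles import degree_counts


def ppi(*edges):
    return InteractionTable("ppi", list(edges))


class TestInducePpi:
    def test_score_threshold_inclusive_at_900(self):
        graph = induce_ppi({"A", "B", "C"},
                           ppi(("A", "B", 950), ("A", "C", 800),
                               ("B", "C", 900)))
        assert set(map(frozenset, graph.edges)) == {
            frozenset({"A", "B"}), frozenset({"B", "C"})
        }

    def test_non_deg_endpoints_excluded(self):
        graph = induce_ppi({"A"}, ppi(("A", "X", 999)))
        assert graph.number_of_edges() == 0

    def test_empty_deg_set_gives_empty_graph(self):
        graph = induce_ppi(set(), ppi(("A", "B", 950)))
        assert graph.number_of_nodes() == 0

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ppi"):
            induce_ppi({"A"}, InteractionTable("tf", [("TF1", "A", None)]))


class TestDegreesAndHubs:
    def test_triangle_degrees(self):
        graph = induce_ppi({"A", "B", "C"},
                           ppi(("A", "B", 950), ("B", "C", 950),
                               ("A", "C", 950)))
        report = node_degrees(graph)
        assert report["degree"].tolist() == [2, 2, 2]

    def test_star_center_is_only_hub_at_threshold_15(self):
        leaves = [f"L{i}" for i in range(16)]
        edges = [("HUB", leaf, 950) for leaf in leaves]
        graph = induce_ppi({"HUB", *leaves}, ppi(*edges))
        hubs = select_hubs(node_degrees(graph), min_degree=15)
        assert hubs["node"].tolist() == ["HUB"]

    def test_strict_rule_rejects_degree_exactly_15(self):
        leaves = [f"L{i}" for i in range(15)]
        graph = induce_ppi({"HUB", *leaves},
                           ppi(*[("HUB", l, 950) for l in leaves]))
        assert select_hubs(node_degrees(graph), min_degree=15).empty
        inclusive = select_hubs(node_degrees(graph), min_degree=15,
                                inclusive=True)
        assert inclusive["node"].tolist() == ["HUB"]

    def test_planted_hub_selected(self):
        table = generate_interaction_table("ppi", 200, ("HUB1", 20), seed=2)
        universe = {a for a, _b, _s in table.edges}
        universe |= {b for _a, b, _s in table.edges}
        graph = induce_ppi(universe, table, min_score=900)
        hubs = select_hubs(node_degrees(graph), min_degree=15)
        assert "HUB1" in hubs["node"].tolist()

    def test_top_k_truncation(self):
        edges = []
        for i, hub in enumerate(["H1", "H2", "H3"]):
            edges += [(hub, f"{hub}L{j}", 950) for j in range(20 - i)]
        nodes = {a for e in edges for a in e[:2]}
        graph = induce_ppi(nodes, ppi(*edges))
        hubs = select_hubs(node_degrees(graph), min_degree=15, top_k=2)
        assert hubs["node"].tolist() == ["H1", "H2"]

    def test_degrees_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(3, 50))
            nodes = [f"N{i}" for i in range(n)]
            m = int(rng.integers(1, 4 * n))
            raw = []
            for _e in range(m):
                a, b = rng.choice(n, size=2, replace=False)
                raw.append((nodes[a], nodes[b]))
            table = ppi(*[(a, b, 950) for a, b in raw])
            graph = induce_ppi(set(nodes), table)
            report = node_degrees(graph)
            expected = degree_counts(raw)
            assert dict(zip(report["node"], report["degree"])) == expected

    def test_duplicate_edge_rows_do_not_inflate_degrees(self):
        graph = induce_ppi({"A", "B"},
                           ppi(("A", "B", 950), ("B", "A", 950)))
        assert node_degrees(graph)["degree"].tolist() == [1, 1]


class TestRegulatorNetworks:
    def tf_table(self, n_targets):
        edges = [("TF1", f"G{i}", None) for i in range(n_targets)]
        return InteractionTable("tf", edges)

    def test_tf_at_inclusive_threshold_selected(self):
        degs = {f"G{i}" for i in range(20)}
        _g, report = regulator_network(degs, self.tf_table(20), "tf",
                                       min_degree=20)
        assert report.loc[report["node"] == "TF1", "selected"].item()

    def test_mirna_below_threshold_rejected(self):
        degs = {f"G{i}" for i in range(14)}
        edges = [("MIR1", f"G{i}", None) for i in range(14)]
        _g, report = regulator_network(
            degs, InteractionTable("mirna", edges), "mirna", min_degree=15
        )
        assert not report.loc[report["node"] == "MIR1", "selected"].item()

    def test_degree_counts_only_deg_targets(self):
        degs = {"G0", "G1"}
        _g, report = regulator_network(degs, self.tf_table(10), "tf")
        assert report.loc[report["node"] == "TF1", "degree"].item() == 2

    def test_regulator_with_no_deg_targets_absent(self):
        graph, report = regulator_network({"X"}, self.tf_table(5), "tf")
        assert report.empty and graph.number_of_nodes() == 0

    def test_bipartite_direction_regulator_to_target(self):
        degs = {f"G{i}" for i in range(5)}
        graph, _ = regulator_network(degs, self.tf_table(5), "tf")
        for a, b in graph.edges:
            assert graph.nodes[a]["type"] == "tf"
            assert graph.nodes[b]["type"] == "gene"

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            regulator_network({"G0"}, self.tf_table(3), "mirna")
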