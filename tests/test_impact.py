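import itertools
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from isonet import dominance, impact, network
from isonet.io import ExpressionMatrix


def call(sample, gene, transcript):
    return dominance.CmdtCall(sample, gene, transcript, 0.9, 5, 0, 0.01, 0.01, 0.1)


def build_net(world):
    return network.build_isoform_network(
        set(world.canonical_fasta),
        world.edges,
        world.domains,
        world.ddi,
        world.isoforms,
        world.canonical_of,
    )


class TestMapDisruptions:
    def make_network(self, statuses):
        return network.IsoformInteractionNetwork(edges=[], statuses=statuses, canonical_of={})

    def status(self, isoform, partner, state):
        return network.IsoformInteractionStatus(
            isoform_id=isoform,
            gene_id="G1",
            partner_protein=partner,
            status=state,
            supporting_domains=frozenset({"d"}),
            matched_domains=frozenset({"d"}) if state == "persists" else frozenset(),
            edge_key=("A", partner),
            combined_score=0.95,
        )

    def test_half_of_edges_lost_is_fifty_percent(self):
        statuses = [
            self.status("P2", "X1", "lost"),
            self.status("P2", "X2", "lost"),
            self.status("P2", "X3", "persists"),
            self.status("P2", "X4", "persists"),
        ]
        records, summary = impact.map_disruptions(
            [call("S1", "G1", "T2")], self.make_network(statuses), {"T2": "P2"}
        )
        assert len(records) == 2
        assert summary.loc[0, "percent_lost"] == 50.0

    def test_isoform_with_all_persisting_yields_no_records(self):
        statuses = [self.status("P2", "X1", "persists")]
        records, summary = impact.map_disruptions(
            [call("S1", "G1", "T2")], self.make_network(statuses), {"T2": "P2"}
        )
        assert records == [] and summary.loc[0, "percent_lost"] == 0.0

    def test_gene_without_network_edges_reported_as_no_ppi_data(self):
        records, summary = impact.map_disruptions(
            [call("S1", "G1", "T2")], self.make_network([]), {"T2": "P2"}
        )
        assert records == []
        assert not bool(summary.loc[0, "ppi_data"])
        assert np.isnan(summary.loc[0, "percent_lost"])

    def test_planted_cohort_mean_equals_total_over_cohort_size(self, default_world):
        w = default_world
        net = build_net(w)
        truth = w.truth_cmdt
        calls = [
            call(r.sample_id, r.gene_id, r.transcript_id)
            for r in truth.itertuples(index=False)
        ]
        records, _ = impact.map_disruptions(calls, net, w.tumor_matrix.transcript_to_protein)
        per_sample = pd.Series([r.sample_id for r in records]).value_counts().to_dict()
        n = len(w.cohort.tumor_samples)
        summary = impact.disruption_summary(per_sample, n)
        assert summary["mean_per_sample"] == pytest.approx(summary["total_disrupted"] / n)
        # planted ground truth: every switch isoform's lost edges, once per sample
        lost_per_isoform = w.truth_lost_edges.groupby("isoform_id").size().to_dict()
        expected_total = sum(
            lost_per_isoform.get(w.tumor_matrix.transcript_to_protein[t], 0)
            for t in truth["transcript_id"]
        )
        assert summary["total_disrupted"] == expected_total


def nds_oracle(graph, source, max_depth=3):
    """BFS-layer enumeration of the density score, independent of the
    implementation's traversal: layers from shortest path lengths, parent
    = lexicographically smallest neighbor in the previous layer."""
    if source not in graph:
        raise KeyError(source)
    lengths = nx.single_source_shortest_path_length(graph, source, cutoff=max_depth)
    total = float(graph.degree(source))
    for node, depth in lengths.items():
        if depth == 0:
            continue
        parents = [p for p in graph.neighbors(node) if lengths.get(p) == depth - 1]
        parent = min(parents)
        total += 2.0**-depth * graph.degree(node) * graph[node][parent]["score"]
    return total


class TestNetworkDensityScore:
    def test_isolated_node_scores_zero(self):
        graph = nx.Graph()
        graph.add_node("A")
        assert impact.network_density_score(graph, "A") == 0.0

    def test_single_edge_hand_value(self):
        graph = nx.Graph()
        graph.add_edge("A", "B", score=1.0)
        assert impact.network_density_score(graph, "A") == pytest.approx(1.5)

    def test_two_branch_path_hand_value(self):
        graph = nx.Graph()
        graph.add_edge("A", "B1", score=0.9)
        graph.add_edge("A", "B2", score=0.9)
        graph.add_edge("B1", "C", score=0.9)
        assert impact.network_density_score(graph, "A") == pytest.approx(3.575)

    def test_unknown_protein_is_error(self):
        with pytest.raises(KeyError):
            impact.network_density_score(nx.Graph(), "Z")

    def test_matches_bfs_layer_oracle_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        for trial in range(100):
            n = int(rng.integers(5, 51))
            p = float(rng.uniform(0.05, 0.3))
            graph = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            graph = nx.relabel_nodes(graph, {i: f"N{i:02d}" for i in graph.nodes})
            for u, v in graph.edges:
                graph[u][v]["score"] = round(float(rng.uniform(0.5, 1.0)), 3)
            for node in graph.nodes:
                assert impact.network_density_score(graph, node) == pytest.approx(
                    nds_oracle(graph, node)
                ), f"trial {trial}, node {node}"

    def test_new_edge_never_decreases_degree_term_and_is_local(self):
        rng = np.random.default_rng(5)
        graph = nx.gnp_random_graph(20, 0.15, seed=11)
        graph = nx.relabel_nodes(graph, {i: f"N{i:02d}" for i in graph.nodes})
        for u, v in graph.edges:
            graph[u][v]["score"] = 0.9
        before = {n: impact.network_density_score(graph, n) for n in graph.nodes}
        before_degree = dict(graph.degree)
        non_edges = [e for e in nx.non_edges(graph)]
        u, v = non_edges[int(rng.integers(len(non_edges)))]
        graph.add_edge(u, v, score=0.9)
        for node in graph.nodes:
            after = impact.network_density_score(graph, node)
            # the degree term never decreases; for the endpoints it grows
            assert graph.degree(node) >= before_degree[node]
            if node in (u, v):
                assert graph.degree(node) == before_degree[node] + 1
            within_3 = (
                nx.shortest_path_length(graph, node, u) <= 3
                if nx.has_path(graph, node, u)
                else False
            ) or (
                nx.shortest_path_length(graph, node, v) <= 3
                if nx.has_path(graph, node, v)
                else False
            )
            if not within_3:
                assert after == pytest.approx(before[node])


class TestRankNds:
    def test_linear_spacing(self):
        entries = impact.rank_nds({"A": 0.0, "B": 5.0, "C": 10.0})
        assert [e.relative_rank for e in entries] == [0.0, 0.5, 1.0]

    def test_all_tied_share_middle_rank(self):
        entries = impact.rank_nds({"A": 3.0, "B": 3.0, "C": 3.0})
        assert [e.relative_rank for e in entries] == [0.5, 0.5, 0.5]

    def test_middle_ties_match_sort_based_oracle(self):
        values = {"A": 1.0, "B": 4.0, "C": 4.0, "D": 9.0, "E": 0.5}
        entries = {e.protein_id: e.relative_rank for e in impact.rank_nds(values)}
        # sort-based oracle: mean ordinal position of each tied block / (N-1)
        ordered = sorted(values, key=lambda k: values[k])
        positions = {}
        for pos, key in enumerate(ordered):
            positions.setdefault(values[key], []).append(pos)
        expected = {
            k: float(np.mean(positions[values[k]])) / (len(values) - 1) for k in values
        }
        assert entries == pytest.approx(expected)

    def test_fewer_than_two_proteins_is_error(self):
        with pytest.raises(ValueError):
            impact.rank_nds({"A": 1.0})


class TestCensusProximity:
    def chain(self):
        graph = nx.Graph()
        graph.add_edge("A", "B", score=0.9)
        graph.add_edge("B", "C", score=0.9)
        graph.add_edge("C", "D", score=0.9)
        return graph

    def test_census_member_has_distance_zero(self):
        records = impact.census_proximity(self.chain(), ["A"], {"A"})
        assert records[0].distance == 0 and records[0].nearest_census_gene == "A"

    def test_direct_neighbor_has_distance_one(self):
        records = impact.census_proximity(self.chain(), ["B"], {"A"})
        assert records[0].distance == 1

    def test_unreachable_gets_sentinel(self):
        graph = self.chain()
        graph.add_node("Z")
        records = impact.census_proximity(graph, ["Z"], {"A"})
        assert records[0].distance == impact.UNREACHABLE

    def test_empty_census_is_error(self):
        with pytest.raises(ValueError):
            impact.census_proximity(self.chain(), ["A"], set())

    def test_distances_match_all_pairs_oracle_on_random_graph(self):
        rng = np.random.default_rng(3)
        graph = nx.gnp_random_graph(10, 0.3, seed=9)
        graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
        census = {"N0", "N3"}
        records = impact.census_proximity(graph, sorted(graph.nodes), census)
        lengths = dict(nx.all_pairs_shortest_path_length(graph))
        for record in records:
            expected = min(
                (lengths[record.protein_id].get(c, np.inf) for c in census),
                default=np.inf,
            )
            if record.distance == impact.UNREACHABLE:
                assert np.isinf(expected)
            else:
                assert record.distance == expected

    def test_adjacent_nodes_differ_by_at_most_one_hop(self):
        graph = nx.gnp_random_graph(30, 0.15, seed=17)
        graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
        census = {"N0"}
        dist = {
            r.protein_id: r.distance
            for r in impact.census_proximity(graph, sorted(graph.nodes), census)
        }
        for u, v in graph.edges:
            if dist[u] != impact.UNREACHABLE and dist[v] != impact.UNREACHABLE:
                assert abs(dist[u] - dist[v]) <= 1


class TestProximityControl:
    def planted_world(self):
        # census hub adjacent to queries; controls live on a far appendage
        graph = nx.Graph()
        graph.add_edge("CEN", "Q1", score=0.9)
        graph.add_edge("CEN", "Q2", score=0.9)
        chain = ["CEN", "H1", "H2", "H3", "H4"]
        for a, b in zip(chain, chain[1:]):
            graph.add_edge(a, b, score=0.9)
        controls = [f"F{i}" for i in range(6)]
        for c in controls:
            graph.add_edge("H4", c, score=0.9)
        tpm = pd.DataFrame(
            {"S1": [10.0] * (2 * len(controls))},
            index=[f"T{i}" for i in range(2 * len(controls))],
        )
        t2g = {f"T{i}": f"F{i // 2}" for i in range(2 * len(controls))}
        t2p = {f"T{2 * i}": c for i, c in enumerate(controls)}
        matrix = ExpressionMatrix(tpm, t2g, t2p)
        return matrix, graph

    def test_planted_near_queries_give_small_p(self):
        matrix, graph = self.planted_world()
        result = impact.proximity_control(
            matrix, graph, {"CEN"}, ["Q1", "Q2", "Q1", "Q2"], n_draws=50, seed=0
        )
        assert result["p_value"] < 0.01
        assert max(result["query_distances"]) == 1
        assert min(result["control_distances"]) >= 5

    def test_zero_draws_is_error(self):
        matrix, graph = self.planted_world()
        with pytest.raises(ValueError):
            impact.proximity_control(matrix, graph, {"CEN"}, ["Q1"], n_draws=0, seed=0)

    def test_null_queries_from_control_pool_are_unbiased(self):
        matrix, graph = self.planted_world()
        pvalues = []
        rng = np.random.default_rng(1)
        controls = [f"F{i}" for i in range(6)]
        for seed in range(20):
            queries = [controls[i] for i in rng.integers(0, 6, size=10)]
            result = impact.proximity_control(
                matrix, graph, {"CEN"}, queries, n_draws=40, seed=seed
            )
            pvalues.append(result["p_value"])
        assert np.median(pvalues) > 0.05  # no systematic shift under the null


class TestEnrichment:
    def records_for(self, sample, pairs):
        return [
            impact.DisruptionRecord(sample, f"T_{a}", f"G_{a}", b, 0.95)
            for a, b in pairs
        ]

    def test_closed_form_hypergeometric(self):
        universe = {f"U{i}" for i in range(7)} | {"A", "B", "C"}
        term = {"A", "B", "C", "U0"}
        records = self.records_for("S1", [("A", "B"), ("B", "C")])
        t2p = {"T_A": "A", "T_B": "B"}
        results = impact.enrich_components(records, {"TERM": term}, universe, t2p)
        assert len(results) == 1
        assert results[0].overlap == 3 and results[0].component_size == 3
        assert results[0].p_value == pytest.approx(comb(4, 3) / comb(10, 3))

    def test_component_disjoint_from_term_has_p_one(self):
        universe = {"A", "B", "X", "Y"}
        records = self.records_for("S1", [("A", "B")])
        results = impact.enrich_components(
            records, {"TERM": {"X", "Y"}}, universe, {"T_A": "A"}
        )
        assert results[0].p_value == pytest.approx(1.0)

    def test_two_disjoint_components_are_independent(self):
        universe = {"A", "B", "C", "D"}
        records = self.records_for("S1", [("A", "B"), ("C", "D")])
        results = impact.enrich_components(
            records, {"TERM": {"A", "B"}}, universe, {"T_A": "A", "T_C": "C"}
        )
        assert len(results) == 2
        assert {r.component_id for r in results} == {0, 1}

    def test_most_significant_term_kept_with_lexicographic_ties(self):
        universe = {"A", "B", "X", "Y"}
        records = self.records_for("S1", [("A", "B")])
        results = impact.enrich_components(
            records,
            {"Z_TERM": {"A", "B"}, "A_TERM": {"A", "B"}, "WEAK": {"X"}},
            universe,
            {"T_A": "A"},
        )
        assert len(results) == 1
        assert results[0].term_id == "A_TERM"

    def test_hypergeometric_matches_enumeration_for_small_universe(self):
        # exact combinatorial check: P(overlap >= k) by enumerating draws
        universe = {f"U{i}" for i in range(12)}
        term = {f"U{i}" for i in range(5)}
        component = {"U0", "U1", "U6", "U7"}
        records = self.records_for(
            "S1", [("U0", "U1"), ("U1", "U6"), ("U6", "U7")]
        )
        t2p = {f"T_{p}": p for p in component}
        results = impact.enrich_components(records, {"TERM": term}, universe, t2p)
        k_observed = len(component & term)
        count = sum(
            1
            for draw in itertools.combinations(sorted(universe), len(component))
            if len(set(draw) & term) >= k_observed
        )
        expected = count / comb(len(universe), len(component))
        assert results[0].p_value == pytest.approx(expected)

    def test_no_records_is_error(self):
        with pytest.raises(ValueError):
            impact.enrich_components([], {"TERM": {"A"}}, {"A"}, {})
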