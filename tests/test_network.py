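"""Co-occurrence network construction, preference coordinates, and stats."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from sipnet.network import (
    CooccurrenceNetwork,
    NodePosition,
    build_network,
    export_graphml,
    import_graphml,
    network_stats,
    node_positions,
    node_table,
)

from conftest import make_table


def brute_force_stats(g: nx.Graph):
    """Independent oracle: triangles by enumeration, paths by BFS."""
    nodes = list(g)
    n = len(nodes)
    mean_degree = 2 * g.number_of_edges() / n
    # local transitivity by neighbor-pair enumeration
    total_c = 0.0
    for v in nodes:
        nbrs = list(g[v])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if g.has_edge(nbrs[i], nbrs[j])
        )
        total_c += 2 * links / (k * (k - 1))
    clustering = total_c / n
    # all-pairs shortest paths by per-source BFS
    path_sum = 0
    connected_pairs = 0
    for src in nodes:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for w in g[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        for tgt, d in dist.items():
            if tgt != src:
                path_sum += d
                connected_pairs += 1
    cpl = path_sum / connected_pairs if connected_pairs else math.nan
    return mean_degree, clustering, cpl


def strategy_table(counts: pd.DataFrame, strategies, compartments):
    meta = pd.DataFrame(
        {
            "species": [f"sp{i}" for i in range(len(counts.index))],
            "strategy": strategies,
            "compartment": compartments,
            "replicate": 1,
        },
        index=counts.index,
    )
    return make_table(counts, None, meta)


class TestBuildNetwork:
    def test_proportional_profiles_get_an_edge(self):
        # one OTU is 3x the other with the same repartition: distance 0
        counts = pd.DataFrame(
            {"a": [10, 20, 30], "b": [30, 60, 90]}, index=["s1", "s2", "s3"]
        )
        net = build_network(make_table(counts), min_prevalence=0.0, threshold=0.12)
        assert [(e[0], e[1]) for e in net.edges] == [("a", "b")]
        assert net.edges[0][2] == pytest.approx(0.0)

    def test_disjoint_supports_no_edge(self):
        counts = pd.DataFrame(
            {"a": [10, 10, 0, 0], "b": [0, 0, 10, 10]},
            index=["s1", "s2", "s3", "s4"],
        )
        net = build_network(make_table(counts), min_prevalence=0.0, threshold=0.12)
        assert net.n_edges == 0

    def test_threshold_one_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 30, size=(4, 6)),
            index=[f"s{i}" for i in range(4)],
            columns=[f"o{i}" for i in range(6)],
        )
        net = build_network(make_table(counts), min_prevalence=0.0, threshold=1.0)
        assert net.n_edges == 6 * 5 // 2

    def test_empty_after_filter_is_valid_empty_network(self, caplog):
        counts = pd.DataFrame({"a": [1, 0, 0, 0]}, index=[f"s{i}" for i in range(4)])
        with caplog.at_level("WARNING"):
            net = build_network(make_table(counts), min_prevalence=0.9)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_edge_set_invariant_to_otu_order_and_rescaling(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.integers(0, 40, size=(6, 10)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"o{i}" for i in range(10)],
        )
        counts += 1  # avoid empty profiles
        base = build_network(make_table(counts), min_prevalence=0.0, threshold=0.3)
        shuffled = counts[list(reversed(counts.columns))]
        scaled = counts.copy()
        scaled["o3"] *= 17
        for variant in (shuffled, scaled):
            net = build_network(make_table(variant), min_prevalence=0.0, threshold=0.3)
            assert {(a, b) for a, b, _ in net.edges} == {
                (a, b) for a, b, _ in base.edges
            }


class TestNodePositions:
    def test_reads_only_in_exploitative_gives_x_one(self):
        counts = pd.DataFrame({"a": [5, 8, 0, 0]}, index=["e1", "e2", "c1", "c2"])
        counts["filler"] = 10  # keeps conservative samples non-empty
        table = strategy_table(
            counts,
            ["exploitative", "exploitative", "conservative", "conservative"],
            ["heavy", "heavy", "heavy", "heavy"],
        )
        pos = node_positions(table)["a"]
        assert pos.x == pytest.approx(1.0)

    def test_equal_heavy_light_gives_y_zero(self):
        counts = pd.DataFrame({"a": [5, 5], "b": [5, 5]}, index=["h1", "l1"])
        table = strategy_table(counts, ["none", "none"], ["heavy", "light"])
        assert node_positions(table)["a"].y == pytest.approx(0.0)

    def test_three_quarters_exploitative_gives_x_half(self):
        # balanced classes, equal depths: 75% of strategy reads exploitative
        counts = pd.DataFrame({"a": [75, 25], "pad": [25, 75]}, index=["e1", "c1"])
        table = strategy_table(
            counts, ["exploitative", "conservative"], ["heavy", "heavy"]
        )
        assert node_positions(table)["a"].x == pytest.approx(0.5)

    def test_undefined_axis_flagged_not_zero(self):
        counts = pd.DataFrame({"a": [0, 0, 4], "pad": [6, 6, 6]}, index=["e1", "c1", "r1"])
        table = strategy_table(
            counts,
            ["exploitative", "conservative", "none"],
            ["heavy", "heavy", "root"],
        )
        pos = node_positions(table)["a"]
        assert pos.x is None  # no reads in either strategy class
        assert pos.y is None  # no reads in heavy or light


class TestNetworkStats:
    def test_printed_network_sizes_reproduce_mean_degrees(self):
        ras = nx.gnm_random_graph(444, 2555, seed=1)
        assert round(network_stats(ras).mean_degree, 3) == 11.509
        root = nx.gnm_random_graph(244, 464, seed=1)
        assert round(network_stats(root).mean_degree, 1) == 3.8

    def test_triangle_graph(self):
        g = nx.complete_graph(3)
        s = network_stats(g)
        assert s.clustering_coefficient == 1.0
        assert s.characteristic_path_length == 1.0

    def test_path_graph_on_three_nodes(self):
        s = network_stats(nx.path_graph(3))
        assert s.clustering_coefficient == 0.0
        assert s.characteristic_path_length == pytest.approx((1 + 1 + 2) / 3)

    def test_mean_degree_identity_and_disconnected_pairs(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("c", "d")])
        s = network_stats(g)
        assert s.mean_degree == 2 * s.n_edges / s.n_nodes
        assert s.n_disconnected_pairs == 4 * 3 - 4

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        p = float(rng.uniform(0.05, 0.4))
        g = nx.gnp_random_graph(n, p, seed=seed)
        s = network_stats(g)
        md, cc, cpl = brute_force_stats(g)
        assert s.mean_degree == md
        assert s.clustering_coefficient == pytest.approx(cc, abs=1e-12)
        if math.isnan(cpl):
            assert math.isnan(s.characteristic_path_length)
        else:
            assert s.characteristic_path_length == pytest.approx(cpl, abs=1e-12)


class TestGraphmlRoundTrip:
    def test_empty_network(self, tmp_path):
        net = CooccurrenceNetwork(nodes={}, edges=[], threshold=0.12)
        path = tmp_path / "empty.graphml"
        export_graphml(net, path)
        back = import_graphml(path)
        assert back.n_nodes == 0 and back.n_edges == 0

    def test_round_trip_preserves_everything(self, tmp_path):
        rng = np.random.default_rng(21)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(6, 8)) + 1,
            index=[f"s{i}" for i in range(6)],
            columns=[f"o{i}" for i in range(8)],
        )
        table = strategy_table(
            counts,
            ["exploitative"] * 3 + ["conservative"] * 3,
            ["heavy", "light", "heavy", "light", "heavy", "light"],
        )
        net = build_network(table, min_prevalence=0.0, threshold=0.5)
        path = tmp_path / "net.graphml"
        export_graphml(net, path)
        back = import_graphml(path)
        assert back.edges == net.edges
        assert back.threshold == net.threshold
        for otu, (phylum, pos) in net.nodes.items():
            b_phylum, b_pos = back.nodes[otu]
            assert b_phylum == phylum
            assert b_pos.x == pytest.approx(pos.x) if pos.x is not None else b_pos.x is None
            assert b_pos.y == pytest.approx(pos.y) if pos.y is not None else b_pos.y is None

    def test_undefined_coordinate_survives_round_trip_as_absent(self, tmp_path):
        net = CooccurrenceNetwork(
            nodes={"o1": ("Firmicutes", NodePosition(x=None, y=0.5))},
            edges=[],
            threshold=0.12,
        )
        path = tmp_path / "net.graphml"
        export_graphml(net, path)
        back = import_graphml(path)
        _, pos = back.nodes["o1"]
        assert pos.x is None
        assert pos.y == pytest.approx(0.5)


def test_node_table_degrees(dataset):
    table, _, _, _ = dataset
    net = build_network(
        table, compartments=("light", "heavy"), position_table=table
    )
    df = node_table(net)
    assert df["degree"].sum() == 2 * net.n_edges
    assert set(df["otu_id"]) == set(net.nodes)
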