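import math

import numpy as np
import pytest

from painnet import metrics as M
from painnet.graph import PainGraph
from painnet.io import aggregate_experiments

from conftest import directed_cycle, make_table, mutual_clique


class TestBuildGraph:
    def test_threshold_drops_weak_edges(self):
        table = aggregate_experiments(
            make_table([("A", "B", "ipsi", "", 0.02), ("B", "A", "ipsi", "", 0.005)])
        )
        g = M.build_graph(table)
        assert g.has_edge("A", "B") and not g.has_edge("B", "A")
        assert g.n_edges == 1

    def test_all_strong_volumes_give_complete_digraph(self):
        rows = [
            (u, v, "ipsi", "", 0.05)
            for u in "ABC"
            for v in "ABC"
            if u != v
        ]
        g = M.build_graph(aggregate_experiments(make_table(rows)))
        assert g.n_edges == 6

    def test_hemispheres_sum_before_thresholding(self):
        table = aggregate_experiments(
            make_table(
                [("A", "B", "ipsi", "", 0.006), ("A", "B", "contra", "", 0.006)]
            )
        )
        assert M.build_graph(table, hemisphere_rule="sum").has_edge("A", "B")
        assert not M.build_graph(table, hemisphere_rule="ipsi").has_edge("A", "B")

    def test_self_projections_dropped(self):
        table = aggregate_experiments(
            make_table([("A", "A", "ipsi", "", 0.9), ("A", "B", "ipsi", "", 0.9)])
        )
        g = M.build_graph(table)
        assert g.n_edges == 1

    def test_isolated_catalog_areas_become_nodes(self):
        table = aggregate_experiments(make_table([("A", "B", "ipsi", "", 0.5)]))
        # catalog inferred from sources/targets only contains A, B here
        assert M.build_graph(table).n_nodes == 2


class TestScalarMetrics:
    def test_density_arithmetic(self):
        g = mutual_clique(["A", "B", "C"])
        assert M.density(g) == 1.0
        lone = PainGraph()
        lone.add_node("A")
        lone.add_node("B")
        assert M.density(lone) == 0.0

    def test_density_undefined_below_two_nodes(self):
        g = PainGraph()
        g.add_node("A")
        with pytest.raises(ValueError):
            M.density(g)

    def test_diameter_of_directed_cycle(self):
        assert M.diameter(directed_cycle(list("ABCDE"))) == 4

    def test_diameter_of_complete_digraph(self):
        assert M.diameter(mutual_clique(list("ABCD"))) == 1

    def test_reciprocity_counts_mutual_edges(self):
        g = PainGraph.from_edges([("A", "B", 1), ("B", "A", 1), ("A", "C", 1)])
        assert M.reciprocity(g) == pytest.approx(2 / 3)
        assert M.reciprocity(mutual_clique(list("ABC"))) == 1.0

    def test_reciprocity_undefined_without_edges(self):
        g = PainGraph()
        g.add_node("A")
        with pytest.raises(ValueError):
            M.reciprocity(g)


class TestCentrality:
    def test_cycle_degrees(self):
        deg = M.degree_centrality(directed_cycle(list("ABCD")))
        assert (deg["total_degree"] == 2).all()
        assert deg["total_degree"].sum() == 2 * 4

    def test_star_degrees(self):
        g = PainGraph.from_edges([("H", leaf, 1) for leaf in "ABC"])
        deg = M.degree_centrality(g)
        assert deg.loc["H", "total_degree"] == 3
        assert (deg.drop("H")["total_degree"] == 1).all()

    def test_closeness_on_directed_cycle(self):
        close = M.closeness_centrality(directed_cycle(list("ABC")))
        for v in close.values():
            assert v == pytest.approx(1 / 3)

    def test_closeness_flags_sink_nodes(self):
        g = PainGraph.from_edges([("A", "B", 1)])
        close = M.closeness_centrality(g)
        assert close["A"] == pytest.approx(1.0)
        assert math.isnan(close["B"])

    def test_betweenness_on_path(self):
        g = PainGraph.from_edges([("A", "B", 1), ("B", "C", 1)])
        btw = M.betweenness_centrality(g)
        assert btw == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_betweenness_mutual_star_matches_enumeration(self):
        leaves = ["L1", "L2", "L3", "L4"]
        g = PainGraph()
        for leaf in leaves:
            g.add_edge("H", leaf)
            g.add_edge(leaf, "H")
        btw = M.betweenness_centrality(g)
        # brute force: enumerate all shortest paths between ordered pairs
        expected = 0
        for s in leaves:
            for t in leaves:
                if s != t:
                    expected += 1  # the unique geodesic s -> H -> t
        assert btw["H"] == expected == 12
        assert all(btw[leaf] == 0 for leaf in leaves)

    def test_top_k_breaks_ties_lexicographically(self):
        ranked = M.top_k({"B": 1.0, "A": 1.0, "C": 2.0, "D": 0.5}, k=3)
        assert ranked == ["C", "A", "B"]


class TestClusteringAssortativity:
    def test_triangle_fully_clustered(self):
        local, mean = M.clustering_coefficients(mutual_clique(list("ABC")))
        assert set(local.values()) == {1.0}
        assert mean == 1.0

    def test_star_hub_unclustered(self):
        g = PainGraph.from_edges([("H", leaf, 1) for leaf in "ABC"])
        local, mean = M.clustering_coefficients(g)
        assert local["H"] == 0.0
        assert mean == 0.0  # only the hub has degree >= 2

    def test_star_is_maximally_disassortative(self):
        g = PainGraph.from_edges([("H", leaf, 1) for leaf in "ABCDE"])
        assert M.assortativity_degree(g) == pytest.approx(-1.0)

    def test_regular_ring_assortativity_undefined(self):
        with pytest.raises(ValueError):
            M.assortativity_degree(directed_cycle(list("ABCDEF")))


class TestDistributions:
    def test_degree_histogram_sums_to_node_count(self):
        g = PainGraph.from_edges([("H", leaf, 1) for leaf in "ABC"])
        hist = M.degree_distribution(g)
        assert sum(hist.values()) == g.n_nodes
        assert hist == {1: 3, 3: 1}

    def test_lorenz_of_regular_sequence_is_diagonal(self):
        x, y = M.lorenz_curve([4, 4, 4, 4])
        np.testing.assert_allclose(x, y)

    def test_lorenz_of_hub_sequence_is_maximally_bowed(self):
        x, y = M.lorenz_curve([0, 0, 0, 9])
        assert y[-2] == 0.0  # all mass on the last node
        assert y[-1] == 1.0

    def test_lorenz_matches_direct_cumsum_recomputation(self):
        rng = np.random.default_rng(3)
        degs = rng.integers(0, 20, size=17)
        degs[0] = 5  # ensure a nonzero total
        x, y = M.lorenz_curve(degs)
        srt = sorted(int(d) for d in degs)
        acc, pts = 0, [0.0]
        for d in srt:
            acc += d
            pts.append(acc / sum(srt))
        np.testing.assert_allclose(y, pts)
        assert np.all(np.diff(y) >= 0) and y[0] == 0.0 and y[-1] == 1.0

    def test_mean_distance_complete_and_cycle(self):
        assert M.mean_distance(mutual_clique(list("ABCD"))).value == 1.0
        md = M.mean_distance(directed_cycle(list("ABCD")))
        assert md.value == pytest.approx(2.0)
        assert md.unreachable_pairs == 0

    def test_mean_distance_counts_unreachable_pairs(self):
        g = PainGraph.from_edges([("A", "B", 1)])
        g.add_node("C")
        md = M.mean_distance(g)
        assert md.value == 1.0
        assert md.unreachable_pairs == 5

    def test_diameter_at_least_mean_distance(self, small_connectome):
        table, _, _ = small_connectome
        g = M.build_graph(aggregate_experiments(table))
        md = M.mean_distance(g)
        assert M.diameter(g) >= md.value >= 1.0


class TestGraphIO:
    def test_graphml_round_trip(self, tmp_path):
        g = PainGraph.from_edges(
            [("A", "B", 0.5), ("B", "A", 1.25), ("B", "C", 3e-3)]
        )
        g.node_attrs["A"].update(group="CH", x=1.0, y=2.0, z=3.0)
        path = tmp_path / "g.graphml"
        g.to_graphml(path)
        back = PainGraph.from_graphml(path)
        assert back.nodes == g.nodes
        assert sorted(back.edges()) == sorted(g.edges())
        assert back.node_attrs["A"]["group"] == "CH"
        assert back.node_attrs["A"]["x"] == 1.0

    def test_edgelist_round_trip(self, tmp_path):
        g = PainGraph.from_edges([("A", "B", 0.5), ("C", "A", 0.125)])
        path = tmp_path / "g.tsv"
        g.to_edgelist_tsv(path)
        back = PainGraph.from_edgelist_tsv(path)
        assert sorted(back.edges()) == sorted(g.edges())

    def test_self_loop_rejected(self):
        g = PainGraph()
        with pytest.raises(ValueError):
            g.add_edge("A", "A")
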