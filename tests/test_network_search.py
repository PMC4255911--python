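import pytest

from kbmine.errors import ParseError, UnknownEntityError, ValidationError
from kbmine.network_search import (PathResult, PenaltyTable, TypedNetwork,
                                   load_typed_network, penalized_search,
                                   rank_nodes, read_quality_table)
from kbmine.synthetic_fixtures import make_network_fixture

from ._oracles import bfs_hops, enumerate_min_penalty


def ppi_triangle() -> tuple[TypedNetwork, PenaltyTable]:
    """Direct two-hybrid edge A–B (penalty 3) vs co-IP route A–C–B (1+1)."""
    network = TypedNetwork()
    network.add_edge("A", "B", "Y2H")
    network.add_edge("A", "C", "coIP")
    network.add_edge("C", "B", "coIP")
    return network, PenaltyTable({"coIP": 1.0, "Y2H": 3.0})


class TestLoadTypedNetwork:
    def test_edges_and_penalties_load(self, tmp_path):
        edges = tmp_path / "edges.tsv"
        edges.write_text("g1\tg2\tcoIP\n")
        penalties = tmp_path / "pen.tsv"
        penalties.write_text("coIP\t1\nY2H\t3\n")
        network, table = load_typed_network(edges, penalties)
        assert network.n_nodes == 2 and network.n_edges == 1
        assert table.penalty("coIP") == 1.0
        assert table.penalty("Y2H") == 3.0

    def test_unlisted_class_falls_back_to_default(self, tmp_path):
        edges = tmp_path / "edges.tsv"
        edges.write_text("g1\tg2\tunseen\n")
        network, table = load_typed_network(edges, None, default_penalty=2.0)
        assert table.penalty("unseen") == 2.0

    def test_node_types_from_fourth_column(self, tmp_path):
        edges = tmp_path / "edges.tsv"
        edges.write_text("g1\td1\tassociated\tgene|disease\n")
        network, _ = load_typed_network(edges)
        assert network.node_type("g1") == "gene"
        assert network.node_type("d1") == "disease"

    def test_empty_edge_table_rejected(self, tmp_path):
        edges = tmp_path / "edges.tsv"
        edges.write_text("# nothing here\n")
        with pytest.raises(ValidationError, match="empty"):
            load_typed_network(edges)

    def test_negative_penalty_rejected(self, tmp_path):
        edges = tmp_path / "edges.tsv"
        edges.write_text("a\tb\tcoIP\n")
        penalties = tmp_path / "pen.tsv"
        penalties.write_text("coIP\t-1\n")
        with pytest.raises(ValidationError, match="negative"):
            load_typed_network(edges, penalties)


class TestPenalizedSearch:
    def test_source_equals_target_gives_zero_length_path(self):
        network, table = ppi_triangle()
        result = penalized_search(network, table, "A", "A")
        assert len(result) == 1
        assert result[0] == PathResult(("A",), (), 0.0)

    def test_two_low_penalty_hops_beat_one_noisy_edge(self):
        network, table = ppi_triangle()
        result = penalized_search(network, table, "A", "B", mode="best")
        assert result.min_penalty == 2.0
        assert len(result) == 1
        assert result[0].nodes == ("A", "C", "B")
        assert result[0].edge_classes == ("coIP", "coIP")

    def test_all_below_returns_both_routes_at_threshold_three(self):
        network, table = ppi_triangle()
        result = penalized_search(network, table, "A", "B",
                                  mode="all_below", threshold=3.0)
        assert [(p.nodes, p.total_penalty) for p in result] == [
            (("A", "C", "B"), 2.0), (("A", "B"), 3.0)]
        assert not result.truncated

    def test_all_below_at_minimum_equals_best_set(self):
        for seed in range(20):
            network, table = make_network_fixture(n_nodes=8, seed=seed)
            nodes = [n for n, _ in network.nodes()]
            best = penalized_search(network, table, nodes[0], nodes[-1], "best")
            below = penalized_search(network, table, nodes[0], nodes[-1],
                                     "all_below", threshold=best.min_penalty)
            assert best.paths == below.paths

    def test_truncation_is_flagged(self):
        network, table = make_network_fixture(
            n_nodes=9, edge_classes=(("coIP", 1.0, 1.0),), seed=0)
        nodes = [n for n, _ in network.nodes()]
        result = penalized_search(network, table, nodes[0], nodes[-1],
                                  "all_below", threshold=8.0, max_paths=3)
        assert result.truncated and len(result) == 3

    def test_unknown_node_and_bad_arguments_rejected(self):
        network, table = ppi_triangle()
        with pytest.raises(UnknownEntityError, match="nope"):
            penalized_search(network, table, "A", "nope")
        with pytest.raises(ValidationError):
            penalized_search(network, table, "A", "B", mode="all_below")
        with pytest.raises(ValidationError):
            penalized_search(network, table, "A", "B", "all_below", threshold=-1)
        with pytest.raises(ValidationError):
            penalized_search(network, table, "A", "B", max_paths=0)

    def test_disconnected_pair_returns_empty_result(self):
        network = TypedNetwork()
        network.add_edge("a", "b", "coIP")
        network.add_node("z")
        result = penalized_search(network, PenaltyTable({"coIP": 1.0}), "a", "z")
        assert len(result) == 0 and result.min_penalty is None


class TestSearchProperties:
    def test_min_penalty_matches_enumeration_oracle(self):
        for seed in range(40):
            network, table = make_network_fixture(n_nodes=7, seed=seed)
            nodes = [n for n, _ in network.nodes()]
            for i in range(len(nodes)):
                for j in range(i, len(nodes)):
                    got = penalized_search(network, table, nodes[i], nodes[j],
                                           max_paths=10000).min_penalty
                    want = enumerate_min_penalty(network, table, nodes[i], nodes[j])
                    assert got == pytest.approx(want), (seed, nodes[i], nodes[j])

    def test_unit_penalties_reduce_to_breadth_first_hops(self):
        for seed in range(20):
            network, _ = make_network_fixture(
                n_nodes=8, edge_classes=(("assoc", 0.2, 1.0),), seed=seed)
            table = PenaltyTable({"assoc": 1.0})
            nodes = [n for n, _ in network.nodes()]
            for j in range(1, len(nodes)):
                got = penalized_search(network, table, nodes[0], nodes[j]).min_penalty
                assert got == bfs_hops(network, nodes[0], nodes[j])

    def test_raising_a_class_penalty_never_shortens_paths(self):
        for seed in range(10):
            network, _ = make_network_fixture(n_nodes=8, seed=seed)
            low = PenaltyTable({"coIP": 1.0, "Y2H": 3.0})
            high = PenaltyTable({"coIP": 1.0, "Y2H": 5.0})
            nodes = [n for n, _ in network.nodes()]
            for j in range(1, len(nodes)):
                before = penalized_search(network, low, nodes[0], nodes[j]).min_penalty
                after = penalized_search(network, high, nodes[0], nodes[j]).min_penalty
                assert after >= before - 1e-12


class TestRankNodes:
    def test_single_node_ranks_first(self):
        ranking = rank_nodes([PathResult(("a",), (), 0.0)], {"a": {"q": 5.0}},
                             {"q": 1.0})
        assert ranking.ranking == (("a", 0.0),)

    def test_higher_quality_wins_on_equal_penalty(self):
        paths = [PathResult(("a", "b"), ("coIP",), 1.0),
                 PathResult(("a", "c"), ("coIP",), 1.0)]
        quality = {"b": {"diseases": 10.0}, "c": {"diseases": 2.0}, "a": {"diseases": 2.0}}
        ranking = rank_nodes(paths, quality, {"diseases": 1.0}, weight_penalty=0.0)
        scores = dict(ranking.ranking)
        assert scores["b"] == 1.0 and scores["c"] == 0.0
        assert ranking.ranking[0][0] == "b"

    def test_zero_weights_rank_by_penalty_alone(self):
        paths = [PathResult(("s", "x"), ("coIP",), 2.0),
                 PathResult(("s", "y"), ("coIP",), 5.0)]
        ranking = rank_nodes(paths, {}, {}, weight_penalty=1.0)
        order = [n for n, _ in ranking.ranking]
        assert order.index("x") < order.index("y")

    def test_all_equal_quality_column_normalizes_to_zero_with_warning(self):
        paths = [PathResult(("a", "b"), ("coIP",), 1.0)]
        quality = {"a": {"q": 3.0}, "b": {"q": 3.0}}
        with pytest.warns(UserWarning, match="all-equal"):
            ranking = rank_nodes(paths, quality, {"q": 1.0}, weight_penalty=0.0)
        assert all(score == 0.0 for _, score in ranking.ranking)

    def test_quality_table_read_from_wide_tsv(self, tmp_path):
        path = tmp_path / "quality.tsv"
        path.write_text("node_id\tdiseases\tvariability\ng1\t4\t0.1\ng2\t2\t0.9\n")
        table = read_quality_table(path)
        assert table["g1"]["diseases"] == 4.0
        assert table["g2"]["variability"] == 0.9
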