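import pytest

from kbmine.descriptors import SemanticDescriptor, parse_descriptor
from kbmine.errors import ValidationError
from kbmine.ontology_graph import ConceptGraph
from kbmine.similarity import (element_score, match_descriptors,
                               rank_candidates)
from kbmine.synthetic_fixtures import make_random_similarity_case

from ._oracles import brute_force_similarity


def graph_with_chain(*curies: str) -> ConceptGraph:
    graph = ConceptGraph()
    for c in curies:
        graph.add_concept(c)
    for a, b in zip(curies, curies[1:]):
        graph.add_relation(a, "related_to", b)
    return graph


class TestElementScore:
    @pytest.mark.parametrize("steps, expected", [(0, 1.0), (1, 0.5), (3, 0.25)])
    def test_damped_values(self, steps, expected):
        assert element_score(steps) == expected

    @pytest.mark.parametrize("steps, expected", [(0, 1.0), (1, 1.0), (2, 0.5), (4, 0.25)])
    def test_literal_values(self, steps, expected):
        assert element_score(steps, score="literal") == expected

    @pytest.mark.parametrize("score", ["damped", "literal"])
    def test_strictly_decreasing_over_positive_steps(self, score):
        values = [element_score(k, score) for k in range(1, 11)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_negative_steps_rejected(self):
        with pytest.raises(ValidationError):
            element_score(-1)


class TestMatchDescriptors:
    def test_self_similarity_is_exactly_one(self):
        graph = graph_with_chain("G:1", "G:2", "G:3")
        d = SemanticDescriptor.from_curies("d", ["G:1", "G:2", "G:3"])
        result = match_descriptors(d, d, graph)
        assert result.sum_scores == 3.0
        assert result.coverage == 1.0
        assert result.normalized == 1.0
        assert all(m.matched_via == "identical" for m in result.element_matches)

    def test_one_step_neighbour_scores_half(self):
        # query {A, B}, target {A, C} with B—C one step apart
        graph = graph_with_chain("O:B", "O:C")
        graph.add_concept("O:A")
        query = SemanticDescriptor.from_curies("q", ["O:A", "O:B"])
        target = SemanticDescriptor.from_curies("t", ["O:A", "O:C"])
        result = match_descriptors(query, target, graph)
        assert result.sum_scores == 1.5
        assert result.coverage == 1.0
        assert result.total == 1.5
        assert result.normalized == 0.75

    def test_unreachable_element_costs_coverage(self):
        graph = graph_with_chain("O:B", "O:C")
        graph.add_concept("O:A")
        graph.add_concept("O:D")
        query = SemanticDescriptor.from_curies("q", ["O:A", "O:B", "O:D"])
        target = SemanticDescriptor.from_curies("t", ["O:A", "O:C"])
        result = match_descriptors(query, target, graph, max_steps=2)
        assert result.sum_scores == 1.5
        assert result.coverage == pytest.approx(2 / 3)
        assert result.total == pytest.approx(1.0)
        assert result.normalized == pytest.approx(1 / 3)
        unmatched = [m for m in result.element_matches if m.matched_via == "unmatched"]
        assert [m.query_element for m in unmatched] == ["O:D"]

    def test_total_equals_sum_times_coverage_invariant(self):
        for seed in range(30):
            graph, query, target, max_steps = make_random_similarity_case(seed)
            r = match_descriptors(query, target, graph, max_steps)
            n = len(query) + len(query.internal_edges)
            assert r.total == pytest.approx(r.sum_scores * r.coverage)
            assert r.normalized == pytest.approx(r.total / n)
            assert 0.0 <= r.normalized <= 1.0

    def test_identical_edges_score_one_and_count_in_coverage(self):
        graph = graph_with_chain("G:1", "G:2")
        d = SemanticDescriptor.from_curies(
            "d", ["G:1", "G:2"], internal_edges=[("G:1", "G:2", "is_a")])
        r = match_descriptors(d, d, graph)
        assert r.edge_matches[0].matched_via == "identical"
        assert r.sum_scores == 3.0  # 2 elements + 1 edge
        assert r.normalized == 1.0

    def test_alternative_edge_class_costs_one_step(self):
        graph = graph_with_chain("G:1", "G:2")
        q = SemanticDescriptor.from_curies(
            "q", ["G:1", "G:2"], internal_edges=[("G:1", "G:2", "is_a")])
        t = SemanticDescriptor.from_curies(
            "t", ["G:1", "G:2"], internal_edges=[("G:1", "G:2", "part_of")])
        r = match_descriptors(q, t, graph)
        assert r.edge_matches[0].matched_via == "similar"
        assert r.edge_matches[0].score == 0.5  # 1 / (1 + 0 + 0 + 1)

    def test_empty_query_rejected(self):
        graph = ConceptGraph()
        with pytest.raises(ValidationError):
            match_descriptors(None, None, graph)

    def test_directionality_documented_asymmetry(self):
        graph = graph_with_chain("O:B", "O:C")
        graph.add_concept("O:A")
        small = SemanticDescriptor.from_curies("s", ["O:A"])
        big = SemanticDescriptor.from_curies("b", ["O:A", "O:B"])
        forward = match_descriptors(small, big, graph)
        backward = match_descriptors(big, small, graph)
        assert forward.normalized == 1.0
        assert backward.normalized == 0.25  # one of two elements recovered


class TestOracleEquivalence:
    def test_matches_exhaustive_assignment_on_random_cases(self):
        for seed in range(60):
            graph, query, target, max_steps = make_random_similarity_case(seed)
            r = match_descriptors(query, target, graph, max_steps)
            want = brute_force_similarity(query, target, graph, max_steps)
            assert r.sum_scores == pytest.approx(want[0], abs=1e-12), seed
            assert r.coverage == pytest.approx(want[1], abs=1e-12), seed
            assert r.total == pytest.approx(want[2], abs=1e-12), seed

    def test_moving_a_target_element_farther_never_helps(self):
        # target element at distances 1 vs 2 from the same query element
        graph = graph_with_chain("O:Q", "O:N1", "O:N2")
        query = SemanticDescriptor.from_curies("q", ["O:Q"])
        near = SemanticDescriptor.from_curies("near", ["O:N1"])
        far = SemanticDescriptor.from_curies("far", ["O:N2"])
        r_near = match_descriptors(query, near, graph)
        r_far = match_descriptors(query, far, graph)
        assert r_far.normalized < r_near.normalized

    def test_coverage_and_normalized_non_decreasing_in_max_steps(self):
        for seed in range(20):
            graph, query, target, _ = make_random_similarity_case(seed)
            previous = None
            for max_steps in range(0, 6):
                r = match_descriptors(query, target, graph, max_steps)
                if previous is not None:
                    assert r.coverage >= previous.coverage - 1e-12
                    assert r.normalized >= previous.normalized - 1e-12
                previous = r


class TestRankCandidates:
    def test_exact_copy_ranks_first_with_score_one(self):
        graph = graph_with_chain("O:Q", "O:N1", "O:N2")
        query = SemanticDescriptor.from_curies("q", ["O:Q"])
        targets = [
            SemanticDescriptor.from_curies("t_far", ["O:N2"]),
            SemanticDescriptor.from_curies("t_same", ["O:Q"]),
            SemanticDescriptor.from_curies("t_near", ["O:N1"]),
        ]
        ranked = rank_candidates(query, targets, graph)
        assert [r.target_id for r in ranked] == ["t_same", "t_near", "t_far"]
        assert [r.normalized for r in ranked] == [1.0, 0.5, pytest.approx(1 / 3)]

    def test_disjoint_target_scores_zero(self):
        graph = ConceptGraph()
        for c in ("A:1", "B:1"):
            graph.add_concept(c)
        query = SemanticDescriptor.from_curies("q", ["A:1"])
        targets = [SemanticDescriptor.from_curies("same", ["A:1"]),
                   SemanticDescriptor.from_curies("other", ["B:1"])]
        ranked = rank_candidates(query, targets, graph)
        assert [(r.target_id, r.normalized) for r in ranked] == \
            [("same", 1.0), ("other", 0.0)]

    def test_top_n_truncates_and_validates(self):
        graph = ConceptGraph()
        graph.add_concept("A:1")
        query = SemanticDescriptor.from_curies("q", ["A:1"])
        targets = [SemanticDescriptor.from_curies(f"t{i}", ["A:1"]) for i in range(5)]
        assert len(rank_candidates(query, targets, graph, top_n=2)) == 2
        with pytest.raises(ValidationError):
            rank_candidates(query, targets, graph, top_n=0)
        with pytest.raises(ValidationError):
            rank_candidates(query, [], graph)
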