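"""Network similarity between semantic descriptors.

A descriptor is treated as a small network of ontology concepts.  Matching
a query descriptor against a target finds, for every query concept, an
identical or similar concept in the target — similarity meaning proximity
in the merged concept graph, with the contribution decaying with the
number of inference steps.  The aggregate follows

    total score = sum(individual scores) * coverage

where individual scores are 1 for identical matches and step-damped for
similar ones, and coverage is the fraction of query objects (elements and
internal edges) actually recovered in the target.  A normalized score in
[0, 1] divides the total by the query size, so a perfect self-match is
exactly 1 (reported as 100%).

Two score functions are available:

``damped`` (default)
    s(0) = 1, s(k) = 1 / (1 + k).  A one-step neighbour scores 0.5,
    strictly below an identical match, preserving the diminishing-
    contribution reading.
``literal``
    s(0) = 1, s(k) = 1 / k — the plain reciprocal-steps rule.  Note its
    k = 1 tie: a one-step neighbour scores 1, indistinguishable from an
    identical match.

Element matching uses an exact optimal one-to-one assignment (each target
element used at most once), with ties between equally scoring assignments
broken lexicographically on (query curie, target curie).  Scores are
computed over the *query's* elements: match(q, t) and match(t, q) may
differ when the two descriptors have different sizes, and both directions
are worth reporting.
"""

from __future__ import annotations

import json
import os
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .descriptors import SemanticDescriptor
from .errors import ValidationError
from .ontology_graph import ConceptGraph, DEFAULT_MAX_STEPS, curie_key

__all__ = [
    "element_score",
    "ElementMatch",
    "EdgeMatch",
    "DescriptorSimilarity",
    "match_descriptors",
    "rank_candidates",
    "write_similarity_tsv",
]

SCORE_FUNCTIONS = ("damped", "literal")


def element_score(steps: int, score: str = "damped") -> float:
    """Score a match found ``steps`` inference steps away.

    0 steps (identical) scores exactly 1; similar matches score
    1/(1+steps) ("damped", default) or 1/steps ("literal").
    """
    if steps is None or int(steps) != steps or steps < 0:
        raise ValidationError(f"steps must be a non-negative integer, got {steps!r}")
    if score not in SCORE_FUNCTIONS:
        raise ValidationError(f"unknown score function {score!r}")
    steps = int(steps)
    if steps == 0:
        return 1.0
    return 1.0 / steps if score == "literal" else 1.0 / (1.0 + steps)


@dataclass(frozen=True)
class ElementMatch:
    query_element: str
    target_element: str | None
    steps: int | None
    score: float
    matched_via: str  # identical | similar | unmatched


@dataclass(frozen=True)
class EdgeMatch:
    query_edge: tuple[str, str, str]
    target_edge: tuple[str, str, str] | None
    score: float
    matched_via: str  # identical | similar | unmatched


@dataclass(frozen=True)
class DescriptorSimilarity:
    """Scored comparison of one query/target descriptor pair."""

    query_id: str
    target_id: str
    element_matches: tuple[ElementMatch, ...]
    edge_matches: tuple[EdgeMatch, ...]
    sum_scores: float
    coverage: float
    total: float
    normalized: float

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "target_id": self.target_id,
            "sum_scores": self.sum_scores,
            "coverage": self.coverage,
            "total": self.total,
            "normalized": self.normalized,
            "element_matches": [
                {"query": m.query_element, "target": m.target_element,
                 "steps": m.steps, "score": m.score, "via": m.matched_via}
                for m in self.element_matches
            ],
            "edge_matches": [
                {"query": list(m.query_edge),
                 "target": list(m.target_edge) if m.target_edge else None,
                 "score": m.score, "via": m.matched_via}
                for m in self.edge_matches
            ],
        }


def _steps_matrix(query: SemanticDescriptor, target: SemanticDescriptor,
                  graph: ConceptGraph, max_steps: int) -> list[list[int | None]]:
    """Pairwise step counts; curies absent from the graph act as isolated
    stubs (distance 0 to themselves, unreachable otherwise)."""
    tkeys = target.keys
    steps: list[list[int | None]] = []
    for qkey, qcurie in zip(query.keys, query.curies):
        if qcurie in graph:
            dist = graph.distances_from(qcurie, max_steps)
            row = [dist.get(tk) for tk in tkeys]
            # a target curie equal to the query's but absent from the graph
            row = [0 if (d is None and tk == qkey) else d
                   for d, tk in zip(row, tkeys)]
        else:
            row = [0 if tk == qkey else None for tk in tkeys]
        steps.append(row)
    return steps


def _best_sum(score_matrix: np.ndarray) -> float:
    if score_matrix.size == 0:
        return 0.0
    rows, cols = linear_sum_assignment(score_matrix, maximize=True)
    return float(score_matrix[rows, cols].sum())


def _lexicographic_optimal_assignment(
        query: SemanticDescriptor, target: SemanticDescriptor,
        scores: np.ndarray) -> dict[int, int]:
    """Pick, among all maximum-score one-to-one assignments, the one that is
    lexicographically smallest on (query curie, target curie) pairs.

    Query elements are fixed in ascending curie order; for each, the
    smallest-curie target that still allows the global optimum is chosen
    (zero-score pairings count as unmatched).  Descriptors are small, so
    the repeated assignment solves are cheap and exact.
    """
    nq, nt = scores.shape
    best = _best_sum(scores)
    order = sorted(range(nq), key=lambda i: query.curies[i])
    assignment: dict[int, int] = {}
    fixed_sum = 0.0
    free_targets = set(range(nt))
    remaining = list(order)
    for qi in order:
        remaining.remove(qi)
        chosen = None
        candidates = sorted((t for t in free_targets if scores[qi, t] > 0),
                            key=lambda t: target.curies[t])
        for ti in candidates:
            rest = scores[np.ix_(remaining, sorted(free_targets - {ti}))]
            if fixed_sum + scores[qi, ti] + _best_sum(rest) >= best - 1e-12:
                chosen = ti
                break
        if chosen is not None:
            assignment[qi] = chosen
            fixed_sum += scores[qi, chosen]
            free_targets.discard(chosen)
    return assignment


def match_descriptors(query: SemanticDescriptor, target: SemanticDescriptor,
                      graph: ConceptGraph, max_steps: int = DEFAULT_MAX_STEPS,
                      score: str = "damped") -> DescriptorSimilarity:
    """Score the similarity of ``target`` to ``query`` over a concept graph.

    Elements are matched by an exact optimal one-to-one assignment of
    query elements to target elements under the step-damped score; internal
    edges are scored afterwards against the matched endpoints.  Aggregates:
    sum_scores is the sum of all element and edge scores, coverage the
    fraction of query objects recovered, total = sum_scores * coverage and
    normalized = total / (number of query elements + edges).
    """
    if query is None or len(query) == 0:
        raise ValidationError("query descriptor must be non-empty")
    if max_steps < 0:
        raise ValidationError(f"max_steps must be >= 0, got {max_steps}")

    steps = _steps_matrix(query, target, graph, max_steps)
    nq, nt = len(query), len(target)
    score_matrix = np.zeros((nq, nt))
    for i in range(nq):
        for j in range(nt):
            if steps[i][j] is not None:
                score_matrix[i, j] = element_score(steps[i][j], score)

    assignment = _lexicographic_optimal_assignment(query, target, score_matrix)

    element_matches = []
    match_of: dict[str, tuple[str, int]] = {}  # query key -> (target curie, steps)
    for i, element in enumerate(query.elements):
        j = assignment.get(i)
        if j is None:
            element_matches.append(ElementMatch(element.curie, None, None, 0.0, "unmatched"))
            continue
        k = steps[i][j]
        via = "identical" if k == 0 else "similar"
        match_of[element.key] = (target.curies[j], k)
        element_matches.append(
            ElementMatch(element.curie, target.curies[j], k,
                         element_score(k, score), via))

    # target edge lookup: canonical endpoint-key pair -> set of classes
    target_edges: dict[tuple[str, str], list[tuple[str, str, str]]] = {}
    for a, b, cls in target.internal_edges:
        ka, kb = sorted((curie_key(a), curie_key(b)))
        target_edges.setdefault((ka, kb), []).append((a, b, cls))

    edge_matches = []
    for a, b, cls in query.internal_edges:
        ma, mb = match_of.get(curie_key(a)), match_of.get(curie_key(b))
        found = None
        if ma is not None and mb is not None:
            ka, kb = sorted((curie_key(ma[0]), curie_key(mb[0])))
            candidates = target_edges.get((ka, kb), [])
            same = [e for e in candidates if e[2] == cls]
            found = same[0] if same else (candidates[0] if candidates else None)
        if found is None:
            edge_matches.append(EdgeMatch((a, b, cls), None, 0.0, "unmatched"))
            continue
        mismatch = 0 if found[2] == cls else 1
        k = ma[1] + mb[1] + mismatch
        via = "identical" if k == 0 else "similar"
        edge_matches.append(EdgeMatch((a, b, cls), found,
                                      1.0 / (1.0 + k) if k else 1.0, via))

    sum_scores = (sum(m.score for m in element_matches)
                  + sum(m.score for m in edge_matches))
    n_objects = nq + len(query.internal_edges)
    n_recovered = (sum(1 for m in element_matches if m.matched_via != "unmatched")
                   + sum(1 for m in edge_matches if m.matched_via != "unmatched"))
    coverage = n_recovered / n_objects
    total = sum_scores * coverage
    normalized = total / n_objects
    return DescriptorSimilarity(
        query.id, target.id, tuple(element_matches), tuple(edge_matches),
        sum_scores, coverage, total, normalized)


def rank_candidates(query: SemanticDescriptor,
                    targets: Sequence[SemanticDescriptor],
                    graph: ConceptGraph, max_steps: int = DEFAULT_MAX_STEPS,
                    top_n: int | None = None,
                    score: str = "damped") -> list[DescriptorSimilarity]:
    """Rank candidate descriptors by normalized similarity to the query.

    Sorted by normalized score descending, ties broken by target id
    ascending; truncated to ``top_n`` when given.
    """
    if not targets:
        raise ValidationError("targets must be non-empty")
    if top_n is not None and top_n <= 0:
        raise ValidationError(f"top_n must be positive, got {top_n}")
    results = [match_descriptors(query, t, graph, max_steps, score) for t in targets]
    results.sort(key=lambda r: (-r.normalized, r.target_id))
    return results[:top_n] if top_n is not None else results


def write_similarity_tsv(results: Sequence[DescriptorSimilarity],
                         path: str | os.PathLike) -> None:
    """Ranked-match TSV: one row per comparison, detail as a JSON column."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write("query_id\ttarget_id\tsum_scores\tcoverage\ttotal\tnormalized\tdetail\n")
        for r in results:
            detail = json.dumps(r.to_dict()["element_matches"], sort_keys=True)
            handle.write(
                f"{r.query_id}\t{r.target_id}\t{r.sum_scores:.6g}\t"
                f"{r.coverage:.6g}\t{r.total:.6g}\t{r.normalized:.6g}\t{detail}\n")
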