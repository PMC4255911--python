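"""Seeded synthetic fixtures for every other module.

All inputs the toolkit consumes — multi-ontology concept graphs, descriptor
pairs with known expected scores, typed penalty networks and pathway
collections with planted groups — can be generated here deterministically,
so the full pipeline is testable without downloading any ontology or
pathway resource.  Identical parameters and seed give byte-identical
serializations.

Expected similarity scores attached to generated descriptor pairs are
exact *by construction*, not by running the similarity algorithm: each
planted pair lives on its own isolated chain component of the concept
graph, so every element's step distance is forced and the optimal
assignment is unique.  None of these generators emulate the statistical
structure of real ontologies (MeSH/SNOMED depth profiles, hub terms) or of
real pathway databases — they provide controlled truth, not realism.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .descriptors import SemanticDescriptor
from .errors import ValidationError
from .network_search import PenaltyTable, TypedNetwork
from .ontology_graph import ConceptGraph
from .pathway_grouping import PathwayCollection, Pathway

__all__ = [
    "FixtureSpec",
    "ExpectedSimilarity",
    "DescriptorPairFixture",
    "make_ontology_fixture",
    "make_random_similarity_case",
    "make_network_fixture",
    "make_pathway_fixture",
]

#: default seed used in documented examples
DEFAULT_SEED = 17

#: element-distance patterns cycled over planted descriptor pairs; None
#: plants an unreachable element
_DISTANCE_PATTERNS: tuple[tuple[int | None, ...], ...] = (
    (0,),
    (0, 1),
    (0, 1, 2),
    (0, 1, 2, None),
)


@dataclass(frozen=True)
class ExpectedSimilarity:
    """Closed-form expected aggregates for a planted descriptor pair."""

    sum_scores: float
    coverage: float
    total: float
    normalized: float
    max_steps: int


@dataclass(frozen=True)
class DescriptorPairFixture:
    query: SemanticDescriptor
    target: SemanticDescriptor
    distances: tuple[int | None, ...]
    expected: ExpectedSimilarity


@dataclass(frozen=True)
class FixtureSpec:
    """Bundle of generator parameters; identical specs give identical fixtures."""

    seed: int = DEFAULT_SEED
    # ontology fixture
    n_ontologies: int = 2
    depth: int = 3
    branching: int = 3
    n_mappings: int = 5
    n_pairs: int = 4
    # network fixture
    n_nodes: int = 12
    edge_classes: tuple[tuple[str, float, float], ...] = (
        ("coIP", 0.15, 1.0), ("Y2H", 0.10, 3.0))
    # pathway fixture
    n_groups: int = 4
    pathways_per_group: int = 10
    universe_size: int = 2000
    within_overlap: float = 0.5

    def build_ontology(self):
        return make_ontology_fixture(self.n_ontologies, self.depth, self.branching,
                                     self.n_mappings, self.seed, n_pairs=self.n_pairs)

    def build_network(self):
        return make_network_fixture(self.n_nodes, self.edge_classes, self.seed)

    def build_pathways(self):
        return make_pathway_fixture(self.n_groups, self.pathways_per_group,
                                    self.universe_size, self.within_overlap, self.seed)


def _expected_scores(distances: Sequence[int | None], max_steps: int) -> ExpectedSimilarity:
    scores = [1.0 if d == 0 else 1.0 / (1.0 + d)
              for d in distances if d is not None and d <= max_steps]
    n = len(distances)
    sum_scores = float(sum(scores))
    coverage = len(scores) / n
    total = sum_scores * coverage
    return ExpectedSimilarity(sum_scores, coverage, total, total / n, max_steps)


def make_ontology_fixture(
    n_ontologies: int = 2, depth: int = 3, branching: int = 3,
    n_mappings: int = 5, seed: int = DEFAULT_SEED, *,
    n_pairs: int = 4, max_steps: int = 3,
) -> tuple[ConceptGraph, list[DescriptorPairFixture]]:
    """Rooted is_a trees with cross-ontology mappings plus planted pairs.

    Builds ``n_ontologies`` trees (prefixes ONT1, ONT2, ...) of the given
    depth and branching factor, connects them with ``n_mappings`` random
    ``mapped_to`` edges, and plants ``n_pairs`` descriptor pairs at
    controlled element distances (cycling 0 / 1 / 2 / unreachable) with
    closed-form expected scores.  Planted chains are isolated components,
    so the expected values are exact.
    """
    if n_ontologies < 1 or depth < 1 or branching < 1:
        raise ValidationError("n_ontologies, depth and branching must all be >= 1")
    if n_mappings < 0 or n_pairs < 0:
        raise ValidationError("n_mappings and n_pairs must be >= 0")
    rng = np.random.default_rng(seed)
    graph = ConceptGraph()

    tree_nodes: list[list[str]] = []
    for o in range(n_ontologies):
        prefix = f"ONT{o + 1}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{prefix}:{counter:07d}"

        root = new_id()
        graph.add_concept(root, f"{prefix} root")
        nodes = [root]
        level = [root]
        for _ in range(depth):
            next_level = []
            for parent in level:
                for _ in range(branching):
                    child = new_id()
                    graph.add_concept(child, f"{prefix} term {counter}")
                    graph.add_relation(child, "is_a", parent)
                    next_level.append(child)
            nodes.extend(next_level)
            level = next_level
        tree_nodes.append(nodes)

    if n_ontologies > 1:
        added = set()
        attempts = 0
        while len(added) < n_mappings and attempts < 50 * max(n_mappings, 1):
            attempts += 1
            a, b = rng.choice(n_ontologies, size=2, replace=False)
            u = tree_nodes[a][int(rng.integers(len(tree_nodes[a])))]
            v = tree_nodes[b][int(rng.integers(len(tree_nodes[b])))]
            if (u, v) in added or (v, u) in added:
                continue
            graph.add_relation(u, "mapped_to", v)
            added.add((u, v))

    pairs: list[DescriptorPairFixture] = []
    for p in range(n_pairs):
        distances = _DISTANCE_PATTERNS[p % len(_DISTANCE_PATTERNS)]
        query_curies, target_curies = [], []
        for e, d in enumerate(distances):
            prefix = f"SYN{p + 1}E{e + 1}"
            if d is None:
                q, t = f"{prefix}:Q", f"{prefix}:T"
                graph.add_concept(q, "synthetic isolated query concept")
                graph.add_concept(t, "synthetic isolated target concept")
            elif d == 0:
                q = t = f"{prefix}:0"
                graph.add_concept(q, "synthetic shared concept")
            else:
                chain = [f"{prefix}:{k}" for k in range(d + 1)]
                for c in chain:
                    graph.add_concept(c, "synthetic chain concept")
                for u, v in zip(chain, chain[1:]):
                    graph.add_relation(u, "related_to", v)
                q, t = chain[0], chain[-1]
            query_curies.append(q)
            target_curies.append(t)
        query = SemanticDescriptor.from_curies(f"model_param_{p + 1}", query_curies)
        target = SemanticDescriptor.from_curies(f"clinical_param_{p + 1}", target_curies)
        pairs.append(DescriptorPairFixture(
            query, target, distances, _expected_scores(distances, max_steps)))
    return graph, pairs


def make_random_similarity_case(
    seed: int, max_query: int = 5, max_target: int = 6, max_concepts: int = 50,
) -> tuple[ConceptGraph, SemanticDescriptor, SemanticDescriptor, int]:
    """Unconstrained random similarity case for oracle-equivalence testing.

    Returns a random concept graph, random query/target descriptors (whose
    elements may or may not be in the graph, may overlap, and may carry
    internal edges) and a random max_steps.  No expected values are
    attached — an independent oracle computes them.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, max_concepts + 1))
    prefixes = ["AAA", "BBB", "CCC"][: int(rng.integers(1, 4))]
    curies = [f"{prefixes[i % len(prefixes)]}:{i:04d}" for i in range(n)]
    graph = ConceptGraph()
    for c in curies:
        graph.add_concept(c, "random concept")
    # random tree skeleton plus extra edges for cycles
    for i in range(1, n):
        j = int(rng.integers(0, i))
        graph.add_relation(curies[i], "is_a", curies[j])
    for _ in range(int(rng.integers(0, n))):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            graph.add_relation(curies[int(i)], "mapped_to", curies[int(j)])

    def random_descriptor(name: str, max_elements: int) -> SemanticDescriptor:
        size = int(rng.integers(1, max_elements + 1))
        pool = list(curies) + [f"XXX:{k}" for k in range(3)]  # some off-graph curies
        chosen = list(rng.choice(len(pool), size=size, replace=False))
        elements = [pool[i] for i in chosen]
        edges = []
        if size >= 2 and rng.random() < 0.5:
            for _ in range(int(rng.integers(1, 3))):
                i, j = rng.choice(size, size=2, replace=False)
                cls = ["is_a", "part_of"][int(rng.integers(0, 2))]
                edges.append((elements[int(i)], elements[int(j)], cls))
        return SemanticDescriptor.from_curies(name, elements, internal_edges=edges)

    query = random_descriptor("query", max_query)
    target = random_descriptor("target", max_target)
    max_steps = int(rng.integers(1, 5))
    return graph, query, target, max_steps


def make_network_fixture(
    n_nodes: int = 12,
    edge_classes: Sequence[tuple[str, float, float]] = (
        ("coIP", 0.15, 1.0), ("Y2H", 0.10, 3.0)),
    seed: int = DEFAULT_SEED,
    default_penalty: float = 1.0,
) -> tuple[TypedNetwork, PenaltyTable]:
    """Random typed network, guaranteed connected.

    Each unordered node pair receives each edge class independently with
    its probability; a random spanning tree of the lowest-penalty class is
    added first so the network is connected.
    """
    if n_nodes < 2:
        raise ValidationError(f"n_nodes must be >= 2, got {n_nodes}")
    penalties = {}
    for cls, prob, pen in edge_classes:
        if not (0 <= prob <= 1):
            raise ValidationError(f"probability for {cls!r} must be in [0,1], got {prob}")
        if pen < 0:
            raise ValidationError(f"penalty for {cls!r} must be >= 0, got {pen}")
        penalties[cls] = float(pen)
    if not penalties:
        raise ValidationError("at least one edge class is required")
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:03d}" for i in range(n_nodes)]
    network = TypedNetwork()
    for node in nodes:
        network.add_node(node, "gene")
    tree_class = min(penalties, key=lambda c: (penalties[c], c))
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        network.add_edge(nodes[i], nodes[j], tree_class)
    for cls, prob, _ in edge_classes:
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < prob:
                    network.add_edge(nodes[i], nodes[j], cls)
    return network, PenaltyTable(penalties, default_penalty)


def make_pathway_fixture(
    n_groups: int = 4, pathways_per_group: int = 10, universe_size: int = 2000,
    within_overlap: float = 0.5, seed: int = DEFAULT_SEED, core_size: int = 40,
) -> tuple[PathwayCollection, tuple[tuple[str, ...], ...]]:
    """Pathway collection with planted overlap groups.

    Each group shares a core member set; each member pathway adds private
    members sized so that the within-group Jaccard is at least
    ``within_overlap`` (cores disjoint across groups, privates drawn from
    the core-free remainder of the universe, so between-group overlap is
    negligible).  Returns the collection and the planted grouping.
    """
    if n_groups < 1 or pathways_per_group < 2:
        raise ValidationError("need n_groups >= 1 and pathways_per_group >= 2")
    if not (0 < within_overlap <= 1):
        raise ValidationError(f"within_overlap must be in (0, 1], got {within_overlap}")
    n_private = int(round(core_size * (1 - within_overlap) / (2 * within_overlap)))
    needed = n_groups * core_size
    if needed + n_private > universe_size:
        raise ValidationError(
            f"universe_size {universe_size} too small: {n_groups} disjoint cores of "
            f"{core_size} plus {n_private} private members need "
            f"{needed + n_private}")
    rng = np.random.default_rng(seed)
    universe = [f"g{i:06d}" for i in range(universe_size)]
    order = rng.permutation(universe_size)
    cores = [frozenset(universe[k] for k in order[g * core_size:(g + 1) * core_size])
             for g in range(n_groups)]
    pool = [universe[k] for k in order[needed:]]

    members: dict[str, frozenset[str]] = {}
    planted: list[tuple[str, ...]] = []
    for g in range(n_groups):
        group_ids = []
        for p in range(pathways_per_group):
            pid = f"PW_{g + 1:02d}_{p + 1:02d}"
            group_ids.append(pid)
            if n_private:
                picked = rng.choice(len(pool), size=n_private, replace=False)
                private = {pool[int(k)] for k in picked}
            else:
                private = set()
            members[pid] = cores[g] | private
        planted.append(tuple(sorted(group_ids)))
    collection = PathwayCollection(
        Pathway(pid, f"synthetic planted pathway (group {pid.split('_')[1]})", m)
        for pid, m in members.items())
    return collection, tuple(planted)
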