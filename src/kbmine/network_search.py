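"""Penalty-weighted search and quality ranking over typed knowledge networks.

A knowledge network carries typed, undirected associations (protein-protein
interaction, gene-disease association, ...).  Each edge class receives a
user-defined non-negative penalty expressing its reliability — e.g. a
co-immunoprecipitation-derived interaction might cost 1 while a two-hybrid
one costs 3 — and path search accumulates penalties so that shorter,
higher-quality routes win.  With unit penalties the search reduces to plain
breadth-first hop counting; with general penalties it is a uniform-cost
(lowest-accumulated-penalty-first) search, the standard generalization.

Two retention modes mirror how results are kept: ``best`` returns every
minimum-penalty simple path, ``all_below`` returns every simple path whose
penalty is at or below a threshold (enumerated depth-first with exact
penalty pruning, valid because penalties are non-negative, and capped at
``max_paths`` with an explicit truncation flag).

Node ranking then re-orders the nodes found by a search using external
quality annotations (number of associated diseases, expression variability,
...): each quality column is min-max normalized across the result nodes and
combined as a weighted sum, minus a weighted, normalized best-path penalty.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import os
import warnings
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import ParseError, UnknownEntityError, ValidationError

__all__ = [
    "TypedNetwork",
    "PenaltyTable",
    "PathResult",
    "PathSearchResult",
    "NodeRanking",
    "load_typed_network",
    "penalized_search",
    "rank_nodes",
    "read_quality_table",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_PATHS = 1000
_EPS = 1e-9


class TypedNetwork:
    """Undirected knowledge graph with typed nodes and class-labelled edges.

    Parallel edges of different classes between the same node pair are kept
    and considered separately by the search; duplicate (a, b, class)
    triples collapse.
    """

    def __init__(self) -> None:
        self._nx = nx.MultiGraph()

    def add_node(self, node: str, node_type: str = "") -> None:
        node = node.strip()
        if not node:
            raise ValidationError("node id must be non-empty")
        if node in self._nx.nodes and node_type and not self._nx.nodes[node].get("type"):
            self._nx.nodes[node]["type"] = node_type
        elif node not in self._nx.nodes:
            self._nx.add_node(node, type=node_type)

    def add_edge(self, a: str, b: str, edge_class: str) -> None:
        a, b, edge_class = a.strip(), b.strip(), edge_class.strip()
        if not a or not b:
            raise ValidationError("edge endpoints must be non-empty")
        if not edge_class:
            raise ValidationError("edge class must be non-empty")
        self.add_node(a)
        self.add_node(b)
        a, b = sorted((a, b))  # canonical storage for the undirected edge
        if not self._nx.has_edge(a, b, key=edge_class):
            self._nx.add_edge(a, b, key=edge_class)

    @property
    def n_nodes(self) -> int:
        return self._nx.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._nx.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self._nx.nodes

    def nodes(self) -> list[tuple[str, str]]:
        return sorted((n, d.get("type", "")) for n, d in self._nx.nodes(data=True))

    def edges(self) -> list[tuple[str, str, str]]:
        return sorted((a, b, k) if a <= b else (b, a, k)
                      for a, b, k in self._nx.edges(keys=True))

    def node_type(self, node: str) -> str:
        if node not in self._nx.nodes:
            raise UnknownEntityError(f"unknown node: {node}")
        return self._nx.nodes[node].get("type", "")

    def neighbors(self, node: str) -> Iterator[tuple[str, str]]:
        """Yield (neighbor, edge_class), sorted for determinism."""
        for v in sorted(self._nx.adj[node]):
            for cls in sorted(self._nx.adj[node][v]):
                yield v, cls


@dataclass(frozen=True)
class PenaltyTable:
    """Per-edge-class penalties; unlisted classes fall back to the default."""

    penalties: Mapping[str, float]
    default_penalty: float = 1.0

    def __post_init__(self):
        for cls, value in self.penalties.items():
            if not (value >= 0):
                raise ValidationError(f"penalty for {cls!r} must be >= 0, got {value}")
        if not (self.default_penalty >= 0):
            raise ValidationError(
                f"default penalty must be >= 0, got {self.default_penalty}")
        object.__setattr__(self, "penalties", dict(self.penalties))

    def penalty(self, edge_class: str) -> float:
        if edge_class not in self.penalties:
            logger.warning("edge class %r not in penalty table; using default %g",
                           edge_class, self.default_penalty)
            return float(self.default_penalty)
        return float(self.penalties[edge_class])


@dataclass(frozen=True)
class PathResult:
    """A simple path with its edge classes and accumulated penalty."""

    nodes: tuple[str, ...]
    edge_classes: tuple[str, ...]
    total_penalty: float

    def __post_init__(self):
        if len(self.edge_classes) != max(len(self.nodes) - 1, 0):
            raise ValidationError("edge_classes must have one entry per hop")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("path must be simple (no repeated node)")


@dataclass(frozen=True)
class PathSearchResult(Sequence):
    """Sequence of :class:`PathResult` plus search metadata."""

    paths: tuple[PathResult, ...]
    truncated: bool
    min_penalty: float | None
    mode: str
    threshold: float | None = None

    def __getitem__(self, index):
        return self.paths[index]

    def __len__(self) -> int:
        return len(self.paths)

    def to_dicts(self) -> list[dict]:
        return [{"nodes": list(p.nodes), "edge_classes": list(p.edge_classes),
                 "total_penalty": p.total_penalty} for p in self.paths]


def _read_rows(path: str | os.PathLike) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8", newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if all(not f.strip() for f in row):
                continue
            yield lineno, row


def load_typed_network(edge_table: str | os.PathLike,
                       penalty_table: str | os.PathLike | None = None,
                       default_penalty: float = 1.0) -> tuple[TypedNetwork, PenaltyTable]:
    """Load a typed network and its penalty table from TSV files.

    Edge table columns: (node_a, node_b, edge_class) with an optional 4th
    column "typeA|typeB".  Penalty table columns: (edge_class, penalty).
    """
    network = TypedNetwork()
    n_edges = 0
    for lineno, row in _read_rows(edge_table):
        if len(row) not in (3, 4):
            raise ParseError(
                f"{edge_table}, row {lineno}: expected 3 or 4 columns, got {len(row)}")
        a, b, cls = row[0], row[1], row[2]
        try:
            network.add_edge(a, b, cls)
        except ValidationError as exc:
            raise ValidationError(f"{edge_table}, row {lineno}: {exc}") from exc
        if len(row) == 4 and "|" in row[3]:
            type_a, type_b = row[3].split("|", 1)
            network.add_node(a.strip(), type_a.strip())
            network.add_node(b.strip(), type_b.strip())
        n_edges += 1
    if n_edges == 0:
        raise ValidationError(f"{edge_table}: empty edge table")

    penalties: dict[str, float] = {}
    if penalty_table is not None:
        for lineno, row in _read_rows(penalty_table):
            if len(row) < 2:
                raise ParseError(
                    f"{penalty_table}, row {lineno}: expected (edge_class, penalty)")
            cls = row[0].strip()
            try:
                value = float(row[1])
            except ValueError as exc:
                raise ParseError(
                    f"{penalty_table}, row {lineno}: penalty {row[1]!r} is not a number"
                ) from exc
            if value < 0:
                raise ValidationError(
                    f"{penalty_table}, row {lineno}: negative penalty {value}")
            penalties[cls] = value
    return network, PenaltyTable(penalties, default_penalty)


def _min_penalty_graph(network: TypedNetwork, penalties: PenaltyTable) -> nx.Graph:
    """Collapse parallel edges to the cheapest class for lower bounds."""
    g = nx.Graph()
    g.add_nodes_from(n for n, _ in network.nodes())
    for a, b, cls in network.edges():
        w = penalties.penalty(cls)
        if not g.has_edge(a, b) or w < g[a][b]["weight"]:
            g.add_edge(a, b, weight=w)
    return g


def _enumerate_paths(network: TypedNetwork, penalties: PenaltyTable,
                     source: str, target: str, bound: float,
                     dist_to_target: Mapping[str, float],
                     max_paths: int) -> tuple[list[PathResult], bool]:
    """DFS over simple paths, pruning when the accumulated penalty plus the
    exact remaining lower bound exceeds ``bound``."""
    results: list[PathResult] = []
    truncated = False
    path = [source]
    classes: list[str] = []
    acc = [0.0]
    on_path = {source}

    def candidates(node: str) -> list[tuple[str, str, float]]:
        return [(v, cls, penalties.penalty(cls)) for v, cls in network.neighbors(node)]

    stack: list[Iterator[tuple[str, str, float]]] = [iter(candidates(source))]
    while stack:
        try:
            v, cls, pen = next(stack[-1])
        except StopIteration:
            stack.pop()
            on_path.discard(path.pop())
            if classes:
                classes.pop()
            acc.pop()
            continue
        if v in on_path:
            continue
        new_acc = acc[-1] + pen
        remaining = 0.0 if v == target else dist_to_target.get(v, math.inf)
        if new_acc + remaining > bound + _EPS:
            continue
        if v == target:
            results.append(PathResult(tuple(path) + (v,), tuple(classes) + (cls,), new_acc))
            if len(results) >= max_paths:
                truncated = True
                break
            continue
        path.append(v)
        classes.append(cls)
        acc.append(new_acc)
        on_path.add(v)
        stack.append(iter(candidates(v)))
    return results, truncated


def penalized_search(network: TypedNetwork, penalties: PenaltyTable,
                     source: str, target: str, mode: str = "best",
                     threshold: float | None = None,
                     max_paths: int = DEFAULT_MAX_PATHS) -> PathSearchResult:
    """Find lowest-penalty or sub-threshold simple paths between two nodes.

    ``best`` returns the complete set of minimum-total-penalty simple paths;
    ``all_below`` returns every simple path with total penalty <= threshold.
    The minimum penalty itself is exact in both modes (uniform-cost search
    on the cheapest-parallel-edge graph).  Results are ordered by
    (total_penalty, node sequence, edge-class sequence); enumeration stops
    at ``max_paths`` with ``truncated=True``.
    """
    for node in (source, target):
        if node not in network:
            raise UnknownEntityError(f"unknown node: {node}")
    if mode not in ("best", "all_below"):
        raise ValidationError(f"mode must be 'best' or 'all_below', got {mode!r}")
    if mode == "all_below":
        if threshold is None:
            raise ValidationError("mode 'all_below' requires a threshold")
        if threshold < 0:
            raise ValidationError(f"threshold must be >= 0, got {threshold}")
    if max_paths < 1:
        raise ValidationError(f"max_paths must be >= 1, got {max_paths}")

    if source == target:
        zero = PathResult((source,), (), 0.0)
        return PathSearchResult((zero,), False, 0.0, mode, threshold)

    lb_graph = _min_penalty_graph(network, penalties)
    dist_to_target = nx.single_source_dijkstra_path_length(lb_graph, target, weight="weight")
    if source not in dist_to_target:
        return PathSearchResult((), False, None, mode, threshold)
    min_penalty = float(dist_to_target[source])

    bound = min_penalty if mode == "best" else float(threshold)
    paths, truncated = _enumerate_paths(network, penalties, source, target,
                                        bound, dist_to_target, max_paths)
    paths.sort(key=lambda p: (p.total_penalty, p.nodes, p.edge_classes))
    return PathSearchResult(tuple(paths), truncated, min_penalty, mode, threshold)


@dataclass(frozen=True)
class NodeRanking:
    """Nodes of a search result ordered by combined quality score."""

    ranking: tuple[tuple[str, float], ...]
    quality_columns: tuple[str, ...]
    weights: Mapping[str, float]
    weight_penalty: float
    normalized_values: Mapping[str, Mapping[str, float]]  # node -> column -> value

    def __iter__(self):
        return iter(self.ranking)

    def __len__(self):
        return len(self.ranking)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, (node, combined) in enumerate(self.ranking, start=1):
            row = {"rank": rank, "node_id": node, "combined_score": combined}
            for col in self.quality_columns:
                row[f"norm_{col}"] = self.normalized_values[node].get(col, 0.0)
            row["norm_penalty"] = self.normalized_values[node].get("__penalty__", 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


def _minmax(values: Mapping[str, float], what: str) -> dict[str, float]:
    if not values:
        return {}
    lo, hi = min(values.values()), max(values.values())
    if hi == lo:
        if len(values) > 1:
            warnings.warn(f"all-equal {what}; normalized to 0 for all nodes")
        return {n: 0.0 for n in values}
    return {n: (v - lo) / (hi - lo) for n, v in values.items()}


def rank_nodes(results: Sequence[PathResult] | PathSearchResult,
               quality_table: Mapping[str, Mapping[str, float]] | pd.DataFrame,
               weights: Mapping[str, float],
               weight_penalty: float = 1.0) -> NodeRanking:
    """Rank the nodes appearing in search results by combined quality.

    combined(n) = sum_c weights[c] * minmax(quality[c])(n)
                  - weight_penalty * minmax(best total_penalty through n)(n)

    Nodes missing from the quality table take neutral normalized value 0;
    an all-equal quality column normalizes to 0 for every node (warning).
    Ordering: combined score descending, node id ascending on ties.
    """
    paths = list(results)
    if not paths:
        raise ValidationError("no paths to rank")
    if isinstance(quality_table, pd.DataFrame):
        df = quality_table.set_index(quality_table.columns[0]) \
            if quality_table.index.name is None and quality_table.columns[0] == "node_id" \
            else quality_table
        quality_table = {str(n): {c: float(v) for c, v in row.items()}
                         for n, row in df.iterrows()}

    nodes = sorted({n for p in paths for n in p.nodes})
    best_pen = {n: min(p.total_penalty for p in paths if n in p.nodes) for n in nodes}

    columns = tuple(weights.keys())
    norm: dict[str, dict[str, float]] = {n: {} for n in nodes}
    for col in columns:
        observed = {n: float(quality_table[n][col]) for n in nodes
                    if n in quality_table and col in quality_table[n]}
        scaled = _minmax(observed, f"quality column {col!r}")
        for n in nodes:
            norm[n][col] = scaled.get(n, 0.0)
    pen_scaled = _minmax(best_pen, "path penalties")
    for n in nodes:
        norm[n]["__penalty__"] = pen_scaled.get(n, 0.0)

    combined = {
        n: sum(weights[c] * norm[n][c] for c in columns)
        - weight_penalty * norm[n]["__penalty__"]
        for n in nodes
    }
    ranking = tuple(sorted(((n, combined[n]) for n in nodes),
                           key=lambda item: (-item[1], item[0])))
    return NodeRanking(ranking, columns, dict(weights), weight_penalty, norm)


def read_quality_table(path: str | os.PathLike) -> dict[str, dict[str, float]]:
    """Read a wide-format TSV quality table (node_id, column..., value...)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a node_id column plus quality columns")
    df = df.set_index(df.columns[0])
    return {str(n): {c: float(v) for c, v in row.items() if pd.notna(v)}
            for n, row in df.iterrows()}
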