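"""Independent naive oracles used to verify the production algorithms.

Everything here is deliberately brute force: plain breadth-first search on
a dict adjacency rebuilt from the public relation list, exhaustive
enumeration of one-to-one assignments, and exhaustive simple-path
enumeration.  Nothing imports the production scoring or search code paths.
"""

from __future__ import annotations

import itertools
from collections import deque


def _key(curie: str) -> str:
    prefix, local = curie.strip().split(":", 1)
    return f"{prefix.strip().casefold()}:{local.strip()}"


def graph_adjacency(graph) -> dict[str, set[str]]:
    """Undirected adjacency over canonical curie keys from graph.relations()."""
    adj: dict[str, set[str]] = {}
    for concept in graph.concepts():
        adj.setdefault(_key(concept.curie), set())
    for rel in graph.relations():
        a, b = _key(rel.subject), _key(rel.object)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def bfs_distance(adj: dict[str, set[str]], a: str, b: str,
                 max_steps: int) -> int | None:
    """Plain BFS step count between two curies, None beyond max_steps."""
    ka, kb = _key(a), _key(b)
    if ka == kb:
        return 0
    if ka not in adj:
        return None
    seen = {ka: 0}
    queue = deque([ka])
    while queue:
        u = queue.popleft()
        if seen[u] == max_steps:
            continue
        for v in adj.get(u, ()):
            if v not in seen:
                seen[v] = seen[u] + 1
                if v == kb:
                    return seen[v]
                queue.append(v)
    return None


def _element_score(steps: int, score: str) -> float:
    if steps == 0:
        return 1.0
    return 1.0 / steps if score == "literal" else 1.0 / (1.0 + steps)


def brute_force_similarity(query, target, graph, max_steps: int,
                           score: str = "damped"):
    """Exhaustively enumerate one-to-one assignments and score the best.

    Returns (sum_scores, coverage, total, normalized) under the same
    aggregation rules the production matcher documents, with ties between
    equally scoring assignments broken lexicographically on
    (query curie, target curie).
    """
    adj = graph_adjacency(graph)
    q_curies, t_curies = list(query.curies), list(target.curies)
    nq, nt = len(q_curies), len(t_curies)
    steps = [[bfs_distance(adj, q, t, max_steps) for t in t_curies]
             for q in q_curies]

    q_order = sorted(range(nq), key=lambda i: q_curies[i])
    slots = list(range(nt)) + [None] * nq
    best_sum = -1.0
    best_key = None
    best_assignment = None
    for perm in itertools.permutations(slots, nq):
        if len({p for p in perm if p is not None}) != sum(p is not None for p in perm):
            continue
        total = 0.0
        for i, j in enumerate(perm):
            if j is not None and steps[i][j] is not None:
                total += _element_score(steps[i][j], score)
        # canonical tie-break key over query elements in curie order;
        # zero-score pairings count as unmatched
        key = tuple(
            t_curies[perm[i]]
            if perm[i] is not None and steps[i][perm[i]] is not None
            else "￿"
            for i in q_order)
        if total > best_sum + 1e-12 or (abs(total - best_sum) <= 1e-12
                                        and (best_key is None or key < best_key)):
            best_sum, best_key, best_assignment = total, key, perm

    matched = {}
    n_matched_elements = 0
    for i, j in enumerate(best_assignment):
        if j is not None and steps[i][j] is not None:
            n_matched_elements += 1
            matched[_key(q_curies[i])] = (_key(t_curies[j]), steps[i][j])

    t_edges: dict[frozenset, list[str]] = {}
    for a, b, cls in target.internal_edges:
        t_edges.setdefault(frozenset((_key(a), _key(b))), []).append(cls)
    edge_sum = 0.0
    n_matched_edges = 0
    for a, b, cls in query.internal_edges:
        ma, mb = matched.get(_key(a)), matched.get(_key(b))
        if ma is None or mb is None:
            continue
        classes = t_edges.get(frozenset((ma[0], mb[0])))
        if not classes:
            continue
        n_matched_edges += 1
        mismatch = 0 if cls in classes else 1
        edge_sum += 1.0 / (1.0 + ma[1] + mb[1] + mismatch)

    n_objects = nq + len(query.internal_edges)
    sum_scores = best_sum + edge_sum
    coverage = (n_matched_elements + n_matched_edges) / n_objects
    total = sum_scores * coverage
    return sum_scores, coverage, total, total / n_objects


def enumerate_min_penalty(network, penalties, source: str, target: str):
    """Minimal total penalty over all simple paths, by full enumeration."""
    if source == target:
        return 0.0
    weight = {}
    for a, b, cls in network.edges():
        w = penalties.penalty(cls)
        key = frozenset((a, b))
        weight[key] = min(w, weight.get(key, float("inf")))
    adj: dict[str, set[str]] = {}
    for key in weight:
        a, b = sorted(key)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    if source not in adj or target not in adj:
        return None

    best = [None]

    def dfs(node, seen, acc):
        if node == target:
            if best[0] is None or acc < best[0]:
                best[0] = acc
            return
        for v in adj.get(node, ()):
            if v not in seen:
                dfs(v, seen | {v}, acc + weight[frozenset((node, v))])

    dfs(source, {source}, 0.0)
    return best[0]


def bfs_hops(network, source: str, target: str):
    """Plain hop-count BFS on the untyped view of a network."""
    if source == target:
        return 0
    adj: dict[str, set[str]] = {}
    for a, b, _ in network.edges():
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, ()):
            if v not in seen:
                seen[v] = seen[u] + 1
                if v == target:
                    return seen[v]
                queue.append(v)
    return None
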