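# Methods

This note documents the models and algorithmic choices behind `kbmine`,
their tunable parameters, and what the synthetic fixtures do and do not
demonstrate.

## Concept graphs and step distance

Ontologies are merged into a single undirected concept graph. Nodes are
concepts identified by CURIEs (`PREFIX:LOCALID`); prefixes are matched
case-insensitively, local ids case-sensitively, and whitespace around the
colon is stripped because both `MESH:D010313` and `NCI: C25378` dialects
occur in practice. Edges are intra-ontology relations (`is_a`,
`part_of`, `xref`, and any `relationship:` class found in an OBO file)
and inter-ontology mappings (`mapped_to` or any predicate whose endpoints
carry different prefixes). Concepts referenced only as relation
endpoints become flagged stub concepts rather than errors, so partial
ontology extracts remain usable.

The distance primitive is the minimum number of edge traversals between
two concepts, computed by breadth-first search with a cutoff. Traversal
is undirected and class-agnostic: a subsumption edge, a cross-reference
and a cross-ontology mapping all cost one step. Nothing in the scoring
model justifies cheaper mapping edges, so uniform cost is the deliberate
minimal assumption; a weighted variant would need evidence about relative
mapping reliability that flat ontology releases do not carry.

**Parameters.** `max_steps` (default 3, dimensionless hops): the
inference horizon. Beyond three hops an element contributes ≤ 0.25 under
the damped score and inferred "similarity" is rarely meaningful; the
horizon also bounds BFS work on large graphs.

## Descriptor similarity

A semantic descriptor is an ordered set of distinct concepts, optionally
with internal edges between its elements. Element order and labels are
carried for reporting only — matching uses identifiers and the concept
graph exclusively.

Matching query *q* against target *t*:

1. Step distances are computed from every query element to every target
   element (≤ `max_steps`; curies absent from the graph act as isolated
   stubs, matching only themselves).
2. Element scores: s(0) = 1 for identical concepts; s(k) = 1/(1+k) for
   concepts k steps apart (the `damped` default). The plain
   reciprocal rule s(k) = 1/k is available as `score="literal"`, but note
   that it makes a one-step neighbour score 1.0 — indistinguishable from
   an identical match — which contradicts the idea of a diminishing
   contribution; the damped form preserves both "identical = 1" and
   strict decay, and is therefore the default.
3. Elements are paired by an exact maximum-weight one-to-one assignment
   (each target element used at most once), solved with the Hungarian
   algorithm. Descriptors are small (typically < 10 elements), so
   exactness is cheap. Ties between equally scoring assignments are
   broken lexicographically on (query curie, target curie), which makes
   results fully deterministic; a zero-score pairing is reported as
   unmatched.
4. Internal edges are scored after elements: an identical edge (same
   endpoints, same class) scores 1; a similar edge scores
   1/(1 + steps(a) + steps(b) + m) where m = 1 on a class mismatch
   (an alternative edge class counts as one extra inference step).
5. Aggregation: `sum_scores` = Σ element scores + Σ edge scores;
   `coverage` = (matched elements + matched edges) / (query elements +
   query edges); `total = sum_scores × coverage`; `normalized = total /
   (query elements + query edges)` ∈ [0, 1]. The denominator includes
   edges whenever the query declares them, so a fully identical match is
   exactly 1 (100%).

Scores are computed over the query's objects, so similarity is
directional: match(q, t) and match(t, q) differ when sizes differ.
Both directions can be reported; no symmetrization is applied because
none is uniquely natural (max, min and mean all discard information).

## Penalized network search

Typed networks are undirected multigraphs: parallel edges of different
classes between the same pair are kept and searched separately.
Penalties are non-negative per-class costs supplied by the user
(`PenaltyTable`; unlisted classes fall back to `default_penalty`, logged).

Minimum total penalty between two nodes is computed by uniform-cost
(Dijkstra) search on the cheapest-parallel-edge graph — the correct
generalization of breadth-first search to non-uniform step costs, and
identical to BFS hop counting when all penalties are 1. Path retention:

* `best` — all minimum-penalty simple paths, found by depth-first
  enumeration pruned with exact distance-to-target lower bounds;
* `all_below` — all simple paths with total penalty ≤ threshold, same
  enumeration with the threshold as bound. The full set can be
  exponential, so enumeration stops at `max_paths` (default 1000) with an
  explicit `truncated` flag — never silently.

Pruning on accumulated penalty is valid because penalties are
non-negative. Results are sorted by (penalty, node sequence, class
sequence) and a source = target query returns the single zero-length
path. Edges are undirected throughout; the association classes this
models (interaction, co-morbidity) are symmetric, and a directed variant
is out of scope.

## Node ranking

Search results are re-ranked by external quality values. For the node
set of the result paths:

```
combined(n) = Σ_c  w_c · minmax(quality_c)(n)  −  w_pen · minmax(best_penalty)(n)
```

where `best_penalty(n)` is the lowest total penalty of any result path
containing *n*, and min-max normalization is over the result nodes.
Nodes missing a quality column take neutral value 0 after normalization;
an all-equal column normalizes to 0 everywhere (warning, no division by
zero). The weighted-sum combination rule and `w_pen` (default 1) are
explicit design choices of this toolkit — quality columns can encode
arbitrarily complex information, and a linear combination with
user-chosen weights is the most transparent way to let the analyst set
the trade-off. Ties order by node id.

## Pathway grouping

Pathways are member sets (GMT files); similarity is the Jaccard index.
The grouping threshold is estimated from a permutation null: each of
`n_perm` (default 1000) null collections redraws every pathway's members
uniformly without replacement from the member universe (the union of all
members), preserving set sizes — the standard null for set-overlap
significance, holding marginal sizes fixed while destroying structure.
For candidate thresholds t (the distinct positive observed pairwise
Jaccard values, scanned ascending),

```
FDR(t) = (mean null pairs ≥ t per permutation) / (observed pairs ≥ t)
```

capped at 1, and the smallest t with FDR(t) ≤ the requested level is
returned. FDR = 0 therefore requires *no* null pair anywhere in all
permutations to reach t — the conservative reading of a 0% cutoff. When
no candidate qualifies (e.g. all pathways disjoint) the result is an
explicit "no admissible threshold" value, not an exception. FDR is
computed over pathway *pairs*; a per-pathway error rate would need an
arbitrary summary of a pathway's many pairs.

Groups are the connected components (size ≥ 2) of the graph joining
pairs with J ≥ threshold. Components rather than cliques: grouping is
meant to partition the collection, and components are the
minimal-assumption partition of a thresholded similarity graph;
singletons are reported separately as ungrouped.

The permutation null is vectorized (per-pathway `argpartition` sampling
into boolean membership matrices, batched matrix products for
intersections), so 1000 permutations of a 40-pathway collection run in
about a second.

## Synthetic fixtures

All test inputs are generated, seeded, and byte-reproducible:

* **Ontology fixture** — rooted `is_a` trees (default 2 ontologies,
  depth 3, branching 3) joined by random `mapped_to` edges, plus
  descriptor pairs planted at controlled element distances
  (0 / 1 / 2 / unreachable). Each planted pair lives on its own isolated
  chain component, so every distance — and hence every expected score —
  is exact by construction, without running the similarity algorithm.
  The trees and mappings exercise graph traversal; the planted pairs
  exercise scoring. A separate generator produces unconstrained random
  graph/descriptor cases for oracle-equivalence tests, whose expected
  values are computed only by a naive exhaustive-assignment oracle kept
  in the test tree.
* **Network fixture** — each node pair receives each edge class
  independently with its probability (defaults: `coIP` p=0.15 penalty 1,
  `Y2H` p=0.10 penalty 3, mirroring the high/low-confidence interaction
  penalty scheme); a random spanning tree of the cheapest class
  guarantees connectivity.
* **Pathway fixture** — default 4 planted groups × 10 pathways over a
  2000-member universe; each group shares a 40-member core and each
  pathway adds 20 private members, giving within-group Jaccard ≥ 0.5 and
  between-group overlap ≈ 0.002 ≤ 0.05. These sizes keep a
  1000-permutation threshold estimation around a second, so the
  100-simulation recovery check completes in minutes on one CPU.

What the fixtures do **not** emulate: the depth/branching statistics and
hub structure of real medical ontologies, the scale-free topology of real
interaction networks, or the heavily nested overlap structure of real
pathway databases. Passing tests demonstrate algorithmic correctness
(agreement with exhaustive oracles, exact recovery of planted structure,
determinism), not that any particular real descriptor pair will score
highly — on real data the attainable similarity is bounded by the
richness of the cross-ontology mapping network available.

## Numerical choices and degenerate inputs

* Scores are plain floats; assignment-optimality and threshold
  comparisons use a 1e-12 slack, path-penalty pruning 1e-9.
* Jaccard values are ratios of small integer counts computed identically
  for observed and null collections (float32 intersections via matrix
  product, exact below 2^24), so threshold comparisons are consistent.
* Degenerate inputs are contracts, not crashes: empty descriptors,
  negative penalties, thresholds outside (0, 1] and unknown identifiers
  raise typed validation/lookup errors; empty graphs, disjoint
  collections and disconnected node pairs return well-defined empty
  results.
* CLI outputs are atomic, seed-pinned and formatted with 6 significant
  digits and "." decimal separator, so double runs are byte-identical.

## Known limitations

* Similarity reproduced on public inputs depends on which inter-ontology
  mappings are loaded; without a rich mapping network (e.g. one derived
  from a metathesaurus) cross-vocabulary scores are conservative.
* `all_below` path enumeration is exponential in the worst case and
  relies on the `max_paths` cap for dense graphs.
* Edge matching scores query edges against the single chosen optimal
  element assignment; it does not trade element score for edge score,
  which keeps the assignment exact and the oracle equivalence clean but
  could under-score contrived edge-heavy descriptors.
* Directed association semantics, OWL reasoning and transitive-closure
  materialization are out of scope.
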