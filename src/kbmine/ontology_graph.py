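"""Multi-ontology concept graphs and the step-distance primitive.

Concepts drawn from several ontologies (anatomy, chemistry, medical subject
headings, ...) are merged into one undirected graph whose edges are
intra-ontology relations (``is_a``, ``part_of``, cross-references) and
inter-ontology mappings (``mapped_to``).  The number of edge traversals
("steps") separating two concepts is the distance primitive behind
ontological inference: concepts a few steps apart are treated as similar,
with similarity decaying as the step count grows.

Traversal is undirected and relation-class-agnostic — every relation,
whether a subsumption edge inside one ontology or a mapping between two,
costs exactly one step.  Curie prefixes are matched case-insensitively
("FMA" and "fma" name the same ontology); local ids are case-sensitive.
"""

from __future__ import annotations

import csv
import json
import os
from collections import deque
from collections.abc import Iterator, Sequence
from dataclasses import dataclass
from typing import IO, Union

import networkx as nx
import obonet

from .errors import ParseError, UnknownEntityError, ValidationError

__all__ = [
    "Concept",
    "ConceptRelation",
    "ConceptGraph",
    "build_concept_graph",
    "concept_distance",
    "normalize_curie",
    "curie_key",
]

#: default traversal horizon; beyond 3 hops inferred similarity is <= 0.25
#: under the damped score function and rarely meaningful
DEFAULT_MAX_STEPS = 3

INTRA = "intra_ontology"
INTER = "inter_ontology"

Source = Union[str, os.PathLike, IO[str]]


def normalize_curie(raw: str) -> str:
    """Normalize a compact identifier "PREFIX:LOCALID".

    Whitespace around the colon is stripped, so the "NCI: C25378" dialect
    normalizes to "NCI:C25378".  Prefix and local id must be non-empty.
    """
    if not isinstance(raw, str):
        raise ValidationError(f"curie must be a string, got {type(raw).__name__}")
    text = raw.strip()
    if ":" not in text:
        raise ValidationError(f"not a curie (missing ':'): {raw!r}")
    prefix, local = text.split(":", 1)
    prefix, local = prefix.strip(), local.strip()
    if not prefix or not local:
        raise ValidationError(f"curie has empty prefix or local id: {raw!r}")
    return f"{prefix}:{local}"


def curie_key(curie: str) -> str:
    """Canonical matching key: prefix case-insensitive, local id case-sensitive."""
    prefix, local = normalize_curie(curie).split(":", 1)
    return f"{prefix.casefold()}:{local}"


@dataclass(frozen=True)
class Concept:
    """An ontology concept: curie, human-readable label and source ontology."""

    curie: str
    label: str = ""
    stub: bool = False  # created only as a dangling relation endpoint

    @property
    def source(self) -> str:
        """Ontology prefix the concept belongs to."""
        return self.curie.split(":", 1)[0]

    @property
    def key(self) -> str:
        return curie_key(self.curie)


@dataclass(frozen=True)
class ConceptRelation:
    """A typed relation between two concepts.

    ``kind`` is derived, never stored independently: a relation is
    inter-ontology exactly when its endpoints carry different prefixes.
    """

    subject: str
    predicate: str
    object: str

    @property
    def kind(self) -> str:
        s = curie_key(self.subject).split(":", 1)[0]
        o = curie_key(self.object).split(":", 1)[0]
        return INTER if s != o else INTRA


class ConceptGraph:
    """Merged multi-ontology concept network.

    Holds concepts keyed by canonical curie and a deduplicated set of
    (subject, predicate, object) relations; maintains an undirected
    networkx view for distance queries.
    """

    def __init__(self) -> None:
        self._concepts: dict[str, Concept] = {}
        self._relations: dict[tuple[str, str, str], ConceptRelation] = {}
        self._nx = nx.Graph()

    # -- construction -------------------------------------------------

    def add_concept(self, curie: str, label: str = "", *, stub: bool = False) -> Concept:
        curie = normalize_curie(curie)
        key = curie_key(curie)
        existing = self._concepts.get(key)
        if existing is not None:
            # upgrade a stub / fill in a label the first time one arrives
            if (existing.stub and not stub) or (not existing.label and label):
                merged = Concept(existing.curie, existing.label or label,
                                 stub=existing.stub and stub)
                self._concepts[key] = merged
                return merged
            return existing
        concept = Concept(curie, label, stub=stub)
        self._concepts[key] = concept
        self._nx.add_node(key)
        return concept

    def add_relation(self, subject: str, predicate: str, object: str) -> ConceptRelation:
        subject = normalize_curie(subject)
        object = normalize_curie(object)
        predicate = predicate.strip()
        if not predicate:
            raise ValidationError("relation predicate must be non-empty")
        for endpoint in (subject, object):
            if curie_key(endpoint) not in self._concepts:
                self.add_concept(endpoint, stub=True)
        triple = (curie_key(subject), predicate, curie_key(object))
        if triple in self._relations:
            return self._relations[triple]
        relation = ConceptRelation(subject, predicate, object)
        self._relations[triple] = relation
        self._nx.add_edge(triple[0], triple[2])
        return relation

    def merge(self, other: "ConceptGraph") -> None:
        for concept in other.concepts():
            self.add_concept(concept.curie, concept.label, stub=concept.stub)
        for rel in other.relations():
            self.add_relation(rel.subject, rel.predicate, rel.object)

    # -- inspection ---------------------------------------------------

    def __contains__(self, curie: str) -> bool:
        try:
            return curie_key(curie) in self._concepts
        except ValidationError:
            return False

    def __len__(self) -> int:
        return len(self._concepts)

    @property
    def n_concepts(self) -> int:
        return len(self._concepts)

    @property
    def n_relations(self) -> int:
        return len(self._relations)

    def get(self, curie: str) -> Concept:
        key = curie_key(curie)
        try:
            return self._concepts[key]
        except KeyError:
            raise UnknownEntityError(f"unknown concept: {normalize_curie(curie)}") from None

    def concepts(self) -> Iterator[Concept]:
        return iter(self._concepts.values())

    def relations(self) -> Iterator[ConceptRelation]:
        return iter(self._relations.values())

    # -- distance primitive -------------------------------------------

    def distances_from(self, curie: str, max_steps: int = DEFAULT_MAX_STEPS) -> dict[str, int]:
        """Breadth-first step counts from ``curie`` to every concept within
        ``max_steps`` hops, keyed by canonical curie key (self included, 0)."""
        if max_steps < 0:
            raise ValidationError(f"max_steps must be >= 0, got {max_steps}")
        start = self.get(curie).key
        dist = {start: 0}
        frontier = deque([start])
        while frontier:
            u = frontier.popleft()
            d = dist[u]
            if d == max_steps:
                continue
            for v in self._nx.adj[u]:
                if v not in dist:
                    dist[v] = d + 1
                    frontier.append(v)
        return dist

    def distance(self, a: str, b: str, max_steps: int = DEFAULT_MAX_STEPS) -> int | None:
        """Minimum number of relation traversals between two concepts.

        Every relation is bidirectional and every relation class costs one
        step.  Returns 0 iff the two curies name the same concept, and None
        when no path of length <= max_steps exists.
        """
        if max_steps < 0:
            raise ValidationError(f"max_steps must be >= 0, got {max_steps}")
        ka, kb = self.get(a).key, self.get(b).key
        if ka == kb:
            return 0
        return self.distances_from(a, max_steps).get(kb)

    # -- (de)serialization --------------------------------------------

    def to_dict(self) -> dict:
        return {
            "concepts": [
                {"curie": c.curie, "label": c.label, "stub": c.stub}
                for c in sorted(self._concepts.values(), key=lambda c: c.key)
            ],
            "relations": [
                {"subject": r.subject, "predicate": r.predicate,
                 "object": r.object, "kind": r.kind}
                for _, r in sorted(self._relations.items())
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ConceptGraph":
        graph = cls()
        for c in data.get("concepts", []):
            graph.add_concept(c["curie"], c.get("label", ""), stub=bool(c.get("stub", False)))
        for r in data.get("relations", []):
            graph.add_relation(r["subject"], r["predicate"], r["object"])
        return graph

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 1)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ConceptGraph":
        return cls.from_dict(json.loads(text))

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(self.to_json())
            handle.write("\n")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ConceptGraph":
        with open(path, encoding="utf-8") as handle:
            return cls.from_json(handle.read())


def _source_name(source: Source) -> str:
    if hasattr(source, "read"):
        return getattr(source, "name", "<stream>")
    return str(source)


def _add_obo(graph: ConceptGraph, source: Source) -> None:
    name = _source_name(source)
    try:
        obo = obonet.read_obo(source, ignore_obsolete=True)
    except Exception as exc:  # obonet raises plain ValueError on bad stanzas
        raise ParseError(f"malformed OBO document {name}: {exc}") from exc
    for node, data in obo.nodes(data=True):
        try:
            graph.add_concept(node, data.get("name", ""))
        except ValidationError as exc:
            raise ParseError(f"invalid term id in {name}: {exc}") from exc
    # obonet edges point child -> parent, keyed by the relation class
    for subject, object_, predicate in obo.edges(keys=True):
        graph.add_relation(subject, predicate, object_)
    for node, data in obo.nodes(data=True):
        for xref in data.get("xref", []):
            token = xref.split()[0] if xref.split() else ""
            if ":" in token:
                try:
                    graph.add_relation(node, "xref", token)
                except ValidationError:
                    continue  # xrefs to URLs etc. are not concept curies


def _iter_table_rows(source: Source) -> Iterator[tuple[int, list[str]]]:
    name = _source_name(source)
    if hasattr(source, "read"):
        rows = csv.reader(source, delimiter="\t")
        for lineno, row in enumerate(rows, start=1):
            yield lineno, row
    else:
        with open(source, encoding="utf-8", newline="") as handle:
            for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
                yield lineno, row


def _add_triple_table(graph: ConceptGraph, source: Source) -> None:
    name = _source_name(source)
    for lineno, row in _iter_table_rows(source):
        if not row or (row[0].lstrip().startswith("#")):
            continue
        if all(not field.strip() for field in row):
            continue
        if len(row) != 3:
            raise ParseError(
                f"{name}, row {lineno}: expected 3 tab-separated columns, got {len(row)}")
        subject, predicate, object_ = (field.strip() for field in row)
        try:
            graph.add_relation(subject, predicate, object_)
        except ValidationError as exc:
            raise ValidationError(f"{name}, row {lineno}: {exc}") from exc


def build_concept_graph(
    obo_sources: Sequence[Source] = (),
    relation_tables: Sequence[Source] = (),
    mapping_tables: Sequence[Source] = (),
) -> ConceptGraph:
    """Build a merged concept graph from OBO documents and triple tables.

    Parameters
    ----------
    obo_sources
        OBO 1.2 flat files (paths or open text handles).  Fields read per
        [Term] stanza: id, name, is_a, relationship, xref; everything else
        is ignored.
    relation_tables, mapping_tables
        UTF-8 TSV files of (subject, predicate, object) triples; lines whose
        first field starts with "#" are skipped.  Both kinds of table are
        parsed identically — whether a triple is intra- or inter-ontology is
        decided by its endpoint prefixes, not by which argument it came in.

    Concepts referenced only as relation endpoints are created as stub
    concepts (empty label, ``stub=True``); duplicate triples collapse.
    """
    graph = ConceptGraph()
    for source in obo_sources:
        _add_obo(graph, source)
    for source in list(relation_tables) + list(mapping_tables):
        _add_triple_table(graph, source)
    return graph


def concept_distance(graph: ConceptGraph, a: str, b: str,
                     max_steps: int = DEFAULT_MAX_STEPS) -> int | None:
    """Module-level alias for :meth:`ConceptGraph.distance`."""
    return graph.distance(a, b, max_steps)
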