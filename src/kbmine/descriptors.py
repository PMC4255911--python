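"""Combinatorial semantic descriptors.

A single ontology term rarely captures the full meaning of a physiological
or clinical parameter.  A semantic descriptor therefore combines several
concepts — ideally from orthogonal ontologies covering substance, anatomy
and quality — into one composite annotation, e.g.::

    MESH:D010313 Partial Pressure; PubChem:977 Oxygen; FMA:83066 Portion of arterial blood

Descriptors are what the similarity search compares: element order is
preserved for reporting but carries no meaning for scoring, and labels are
never used in matching (matching is identifier- and graph-based only).
"""

from __future__ import annotations

import csv
import os
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from .errors import ParseError, ValidationError
from .ontology_graph import curie_key, normalize_curie

__all__ = [
    "DescriptorElement",
    "SemanticDescriptor",
    "parse_descriptor",
    "render_descriptor",
    "read_descriptor_table",
    "write_descriptor_table",
]


@dataclass(frozen=True)
class DescriptorElement:
    curie: str
    label: str = ""

    @property
    def key(self) -> str:
        return curie_key(self.curie)


@dataclass(frozen=True)
class SemanticDescriptor:
    """A parameter's combinatorial annotation.

    ``elements`` is an ordered collection of distinct concepts;
    ``internal_edges`` optionally relates elements to one another
    (endpoints must be members).  The worked descriptor examples carry no
    edges, so edges default to empty and all edge-aware scoring degrades
    gracefully.
    """

    id: str
    elements: tuple[DescriptorElement, ...]
    internal_edges: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self):
        if not self.elements:
            raise ValidationError(f"descriptor {self.id!r} has no elements")
        keys = [e.key for e in self.elements]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(
                f"descriptor {self.id!r} has duplicate curies: {', '.join(dupes)}")
        member = set(keys)
        norm_edges = []
        for a, b, cls in self.internal_edges:
            a, b = normalize_curie(a), normalize_curie(b)
            for endpoint in (a, b):
                if curie_key(endpoint) not in member:
                    raise ValidationError(
                        f"descriptor {self.id!r}: edge endpoint {endpoint} "
                        "is not an element")
            norm_edges.append((a, b, cls))
        object.__setattr__(self, "internal_edges", tuple(norm_edges))

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def curies(self) -> tuple[str, ...]:
        return tuple(e.curie for e in self.elements)

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(e.key for e in self.elements)

    @classmethod
    def from_curies(cls, id: str, curies: Iterable[str],
                    labels: Iterable[str] | None = None,
                    internal_edges: Iterable[tuple[str, str, str]] = ()) -> "SemanticDescriptor":
        curies = list(curies)
        labels = list(labels) if labels is not None else [""] * len(curies)
        elements = tuple(DescriptorElement(normalize_curie(c), l)
                         for c, l in zip(curies, labels))
        return cls(id, elements, tuple(internal_edges))

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "elements": [{"curie": e.curie, "label": e.label} for e in self.elements],
            "edges": [list(edge) for edge in self.internal_edges],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SemanticDescriptor":
        elements = tuple(DescriptorElement(normalize_curie(e["curie"]), e.get("label", ""))
                         for e in data["elements"])
        edges = tuple(tuple(edge) for edge in data.get("edges", []))
        return cls(data["id"], elements, edges)


def parse_descriptor(text: str, id: str = "descriptor") -> SemanticDescriptor:
    """Parse the semicolon-separated descriptor dialect.

    Fragments are split on ";"; within a fragment the curie is the first
    whitespace token containing ":" (whitespace after the colon is
    tolerated, so "NCI: C25378" works) and the remaining text is the label.
    Order is preserved; duplicate curies are rejected.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValidationError("descriptor text must be non-empty")
    elements: list[DescriptorElement] = []
    for fragment in text.split(";"):
        fragment = fragment.strip()
        if not fragment:
            continue
        tokens = fragment.split()
        curie_idx = next((i for i, tok in enumerate(tokens) if ":" in tok), None)
        if curie_idx is None:
            raise ParseError(f"fragment without a curie token: {fragment!r}")
        curie_tok = tokens[curie_idx]
        rest = tokens[:curie_idx] + tokens[curie_idx + 1:]
        # "NCI: C25378" — colon token with empty local id takes the next token
        if curie_tok.rstrip().endswith(":"):
            if not rest or curie_idx >= len(tokens) - 1:
                raise ParseError(f"fragment with incomplete curie: {fragment!r}")
            curie_tok = curie_tok + tokens[curie_idx + 1]
            rest = tokens[:curie_idx] + tokens[curie_idx + 2:]
        try:
            curie = normalize_curie(curie_tok)
        except ValidationError as exc:
            raise ParseError(f"fragment with invalid curie: {fragment!r} ({exc})") from exc
        elements.append(DescriptorElement(curie, " ".join(rest)))
    if not elements:
        raise ValidationError("descriptor text contains no fragments")
    return SemanticDescriptor(id, tuple(elements))


def render_descriptor(descriptor: SemanticDescriptor) -> str:
    """Inverse of :func:`parse_descriptor` for edge-free descriptors."""
    return "; ".join(
        f"{e.curie} {e.label}".strip() for e in descriptor.elements)


def read_descriptor_table(path: str | os.PathLike) -> list[SemanticDescriptor]:
    """Read a TSV batch file with columns (parameter_id, descriptor_text)."""
    descriptors = []
    seen: set[str] = set()
    with open(path, encoding="utf-8", newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) < 2:
                raise ParseError(
                    f"{path}, row {lineno}: expected (parameter_id, descriptor_text)")
            param_id, text = row[0].strip(), row[1]
            if param_id in seen:
                raise ValidationError(f"{path}, row {lineno}: duplicate id {param_id!r}")
            seen.add(param_id)
            descriptors.append(parse_descriptor(text, id=param_id))
    if not descriptors:
        raise ValidationError(f"{path}: no descriptors found")
    return descriptors


def write_descriptor_table(descriptors: Sequence[SemanticDescriptor],
                           path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for d in descriptors:
            writer.writerow([d.id, render_descriptor(d)])
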