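import textwrap

import pytest

from kbmine.ontology_graph import ConceptGraph, build_concept_graph


@pytest.fixture
def chain_graph() -> ConceptGraph:
    """X — Y — Z chain used for distance cutoff tests."""
    graph = ConceptGraph()
    for curie in ("T:X", "T:Y", "T:Z"):
        graph.add_concept(curie)
    graph.add_relation("T:X", "is_a", "T:Y")
    graph.add_relation("T:Y", "is_a", "T:Z")
    return graph


@pytest.fixture
def tiny_obo(tmp_path):
    path = tmp_path / "tiny.obo"
    path.write_text(textwrap.dedent("""\
        format-version: 1.2

        [Term]
        id: T:1
        name: parent term

        [Term]
        id: T:2
        name: child term
        is_a: T:1
        """))
    return path


@pytest.fixture
def mapping_graph() -> ConceptGraph:
    """Cross-ontology graph mirroring a descriptor-mapping scenario:
    a MeSH pressure concept mapped to two NCI concepts, and two FMA
    anatomy concepts one subsumption step apart."""
    graph = build_concept_graph()
    graph.add_concept("MESH:D010313", "Partial Pressure")
    graph.add_concept("PubChem:977", "Oxygen")
    graph.add_concept("FMA:83066", "Portion of arterial blood")
    graph.add_concept("NCI:C25378", "Partial")
    graph.add_concept("NCI:C25195", "Pressure")
    graph.add_concept("FMA:45623", "Systemic arterial system")
    graph.add_relation("MESH:D010313", "mapped_to", "NCI:C25378")
    graph.add_relation("MESH:D010313", "mapped_to", "NCI:C25195")
    graph.add_relation("FMA:83066", "part_of", "FMA:45623")
    return graph
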