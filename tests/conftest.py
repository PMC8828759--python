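import pytest

from oncomatch.graph import (
    EvidenceItem,
    KnowledgeGraph,
    OntologyEdge,
    OntologyTerm,
    Statement,
)
from oncomatch.simulate import FixtureSizes, build_fixture, write_fixture


@pytest.fixture(scope="session")
def default_bundle():
    return build_fixture(123)


@pytest.fixture(scope="session")
def fixture_paths(default_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return write_fixture(default_bundle, out)


def make_term(source="src", source_id="t1", name="term", version="", term_class="therapy", is_alias=False):
    return OntologyTerm(source, source_id, name, version, term_class, is_alias)


@pytest.fixture()
def drug_graph():
    """imatinib (ncit) <-alias- imatinib mesylate (drugbank); isolated nilotinib."""
    graph = KnowledgeGraph()
    a = graph.add_term(OntologyTerm("ncit", "C1234", "Imatinib", "v1", "therapy"))
    b = graph.add_term(
        OntologyTerm("drugbank", "DB0001", "Imatinib Mesylate", "", "therapy", True)
    )
    c = graph.add_term(OntologyTerm("ncit", "C9999", "Nilotinib", "", "therapy"))
    graph.add_edge(OntologyEdge(b, a, "alias_of", "drugbank"))
    return graph, a, b, c


@pytest.fixture()
def kras_graph():
    """Worked second-pass example: S1 (KRAS p.G12D => oncogenic KRAS) and S2
    (oncogenic mutations in KRAS => resistance to a drug), plus S3 chained on
    S2's conclusion, which single-hop inference must never reach."""
    graph = KnowledgeGraph()
    kras = graph.add_term(OntologyTerm("hgnc", "6407", "KRAS", "", "gene"))
    onco = graph.add_term(OntologyTerm("vocab", "r1", "oncogenic", "", "relevance_term"))
    resist = graph.add_term(OntologyTerm("vocab", "r2", "resistance", "", "relevance_term"))
    sens = graph.add_term(OntologyTerm("vocab", "r3", "sensitivity", "", "relevance_term"))
    drug = graph.add_term(OntologyTerm("drugsa", "d1", "cetuximab", "", "therapy"))
    drug2 = graph.add_term(OntologyTerm("drugsa", "d2", "othermab", "", "therapy"))
    spec_cond = graph.add_term(
        OntologyTerm("vclass", "v1", "KRAS:p.G12D", "", "variant_class")
    )
    gene_cond = graph.add_term(
        OntologyTerm("vclass", "v2", "KRAS mutation", "", "variant_class")
    )
    char_cond = graph.add_term(
        OntologyTerm("vclass", "v3", "oncogenic mutations in KRAS", "", "variant_class")
    )
    chain_cond = graph.add_term(
        OntologyTerm("vclass", "v4", "resistance mutations in KRAS", "", "variant_class")
    )
    evidence = (EvidenceItem("PMID:1", ("civic", "A")),)
    graph.add_statement(
        Statement("S1", (spec_cond,), kras, onco, evidence, "civic", "biological")
    )
    graph.add_statement(
        Statement("S2", (char_cond,), drug, resist, evidence, "civic", "therapeutic")
    )
    graph.add_statement(
        Statement("S3", (chain_cond,), drug2, sens, evidence, "oncokb", "therapeutic")
    )
    graph.add_statement(
        Statement("S4", (gene_cond,), drug, sens, evidence, "oncokb", "therapeutic")
    )
    return graph
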