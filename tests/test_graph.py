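import random

import pytest

from oncomatch.errors import (
    InvariantError,
    NoMatchError,
    ProvenanceCollisionError,
    ReferentialIntegrityError,
)
from oncomatch.graph import (
    EvidenceItem,
    KnowledgeGraph,
    OntologyEdge,
    OntologyTerm,
    Statement,
)


class TestAddTerm:
    def test_round_trip_by_key(self):
        graph = KnowledgeGraph()
        term = OntologyTerm("ncit", "C1234", "Imatinib", "v1", "therapy")
        key = graph.add_term(term)
        assert key == ("ncit", "C1234", "v1")
        assert graph.term(key) == term

    def test_duplicate_key_collides(self):
        graph = KnowledgeGraph()
        graph.add_term(OntologyTerm("ncit", "C1234", "Imatinib", "v1", "therapy"))
        with pytest.raises(ProvenanceCollisionError):
            graph.add_term(OntologyTerm("ncit", "C1234", "Other name", "v1", "therapy"))

    def test_same_id_different_version_is_distinct(self):
        graph = KnowledgeGraph()
        graph.add_term(OntologyTerm("ncit", "C1", "a", "v1", "therapy"))
        graph.add_term(OntologyTerm("ncit", "C1", "a", "v2", "therapy"))
        assert len(graph) == 2

    def test_batch_counts_per_source(self):
        # oracle: independent scan of the generated input records
        records = [
            OntologyTerm(source, f"id{i}", f"name {source} {i}", "", "therapy")
            for source in ("alpha", "beta", "gamma")
            for i in range(100)
        ]
        graph = KnowledgeGraph()
        for record in records:
            graph.add_term(record)
        expected = {}
        for record in records:
            expected[record.source] = expected.get(record.source, 0) + 1
        got = {}
        for term in graph.terms():
            got[term.source] = got.get(term.source, 0) + 1
        assert got == expected == {"alpha": 100, "beta": 100, "gamma": 100}

    def test_empty_name_rejected(self):
        with pytest.raises(InvariantError):
            OntologyTerm("ncit", "C1", "   ", "", "therapy")

    def test_unknown_class_rejected(self):
        with pytest.raises(InvariantError):
            OntologyTerm("ncit", "C1", "x", "", "not-a-class")


class TestFindTermsByName:
    def test_whitespace_and_case_normalized(self, drug_graph):
        graph, a, b, c = drug_graph
        assert graph.find_terms_by_name(" ImAtInIb ") == {a}

    def test_no_match_is_an_error(self, drug_graph):
        graph, *_ = drug_graph
        with pytest.raises(NoMatchError):
            graph.find_terms_by_name("absent-drug")

    def test_ambiguity_set_returned_in_full(self):
        # oracle: linear scan comparing normalized names
        graph = KnowledgeGraph()
        keys = [
            graph.add_term(OntologyTerm(source, "x", "Imatinib", "", "therapy"))
            for source in ("ncit", "drugbank")
        ]
        scan = {
            term.key
            for term in graph.terms()
            if term.name.strip().lower() == "imatinib"
        }
        assert graph.find_terms_by_name("imatinib") == set(keys) == scan

    def test_class_restriction(self, drug_graph):
        graph, a, *_ = drug_graph
        assert graph.find_terms_by_name("imatinib", term_class="therapy") == {a}
        with pytest.raises(NoMatchError):
            graph.find_terms_by_name("imatinib", term_class="disease")


def _statement(graph, sid, conditions, subject, relevance, category="therapeutic"):
    return Statement(
        sid,
        tuple(conditions),
        subject,
        relevance,
        (EvidenceItem("PMID:1"),),
        "civic",
        category,
    )


class TestStatements:
    @pytest.fixture()
    def terms(self):
        graph = KnowledgeGraph()
        cond1 = graph.add_term(OntologyTerm("vclass", "v1", "KRAS mutation", "", "variant_class"))
        cond2 = graph.add_term(OntologyTerm("ncit", "D1", "colorectal cancer", "", "disease"))
        drug = graph.add_term(OntologyTerm("drugsa", "d1", "drug", "", "therapy"))
        rel = graph.add_term(OntologyTerm("vocab", "r1", "sensitivity", "", "relevance_term"))
        return graph, cond1, cond2, drug, rel

    def test_schema_conformant_statement_accepted(self, terms):
        graph, cond1, cond2, drug, rel = terms
        sid = graph.add_statement(_statement(graph, "S1", [cond1, cond2], drug, rel))
        assert graph.statement(sid).subject == drug

    def test_zero_conditions_rejected(self, terms):
        graph, _, _, drug, rel = terms
        with pytest.raises(InvariantError):
            _statement(graph, "S1", [], drug, rel)

    def test_zero_evidence_rejected(self, terms):
        graph, cond1, _, drug, rel = terms
        with pytest.raises(InvariantError):
            Statement("S1", (cond1,), drug, rel, (), "civic", "therapeutic")

    def test_dangling_reference_rejected(self, terms):
        graph, cond1, _, drug, rel = terms
        with pytest.raises(ReferentialIntegrityError):
            graph.add_statement(
                _statement(graph, "S1", [cond1, ("ghost", "id", "")], drug, rel)
            )

    def test_category_consistency_enforced(self, terms):
        graph, cond1, _, drug, rel = terms
        # "sensitivity" is assigned therapeutic at load time
        with pytest.raises(InvariantError):
            graph.add_statement(
                _statement(graph, "S1", [cond1], drug, rel, category="prognostic")
            )

    def test_reverse_index_agrees_with_scan(self, default_bundle):
        graph = default_bundle.graph
        checked = 0
        for term in graph.terms():
            indexed = graph.statements_for_condition(term.key)
            scanned = {
                stmt.statement_id
                for stmt in graph.statements()
                if term.key in stmt.conditions
            }
            assert indexed == scanned
            checked += 1
        assert checked == len(graph)


class TestValidate:
    def test_empty_graph_is_clean(self):
        assert KnowledgeGraph().validate() == []

    def test_default_fixture_is_clean(self, default_bundle):
        assert default_bundle.graph.validate() == []

    def test_single_dangling_edge_reported(self, drug_graph):
        graph, a, *_ = drug_graph
        graph._edges.append(OntologyEdge(a, ("ghost", "g", ""), "cross_reference"))
        violations = graph.validate()
        assert len(violations) == 1
        assert violations[0].kind == "dangling_edge"

    def test_alias_without_edge_reported(self):
        graph = KnowledgeGraph()
        graph.add_term(OntologyTerm("x", "1", "orphan alias", "", "therapy", True))
        assert [v.kind for v in graph.validate()] == ["alias_without_edge"]

    def test_injected_corruption_is_fully_recovered(self, default_bundle):
        # oracle: the corruption script records exactly what it injects
        rng = random.Random(99)
        graph = KnowledgeGraph()
        bundle_graph = default_bundle.graph
        for term in bundle_graph.terms():
            graph.add_term(term)
        for edge in bundle_graph.edges:
            graph.add_edge(edge)
        expected_kinds = []
        terms = sorted(graph._terms)
        for _ in range(5):
            src = rng.choice(terms)
            graph._edges.append(OntologyEdge(src, ("ghost", str(rng.random()), ""), "subclass_of"))
            expected_kinds.append("dangling_edge")
        got = [v.kind for v in graph.validate()]
        assert sorted(got) == sorted(expected_kinds)
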