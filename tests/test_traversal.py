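import random

import pytest
from hypothesis import given, strategies as st

from oncomatch.errors import NoMatchError, ReferentialIntegrityError
from oncomatch.graph import KnowledgeGraph, OntologyEdge, OntologyTerm
from oncomatch.traversal import (
    canonical_representative,
    expand_diagnosis,
    expand_terms,
    normalize_label,
    representative_map,
)

from .oracles import union_find_partition


class TestNormalizeLabel:
    def test_strip_and_lowercase(self):
        assert normalize_label("  Imatinib Mesylate ") == "imatinib mesylate"

    def test_empty(self):
        assert normalize_label("") == ""

    def test_already_normal(self):
        assert normalize_label("kras") == "kras"

    @given(st.text(max_size=80))
    def test_idempotent(self, text):
        assert normalize_label(normalize_label(text)) == normalize_label(text)


@pytest.fixture()
def chain_graph():
    """A -alias_of- B -cross_reference- C; D isolated."""
    graph = KnowledgeGraph()
    a = graph.add_term(OntologyTerm("s", "A", "a term", "", "therapy", True))
    b = graph.add_term(OntologyTerm("s", "B", "b term", "", "therapy"))
    c = graph.add_term(OntologyTerm("t", "C", "c term", "", "therapy"))
    d = graph.add_term(OntologyTerm("t", "D", "d term", "", "therapy"))
    graph.add_edge(OntologyEdge(a, b, "alias_of", "s"))
    graph.add_edge(OntologyEdge(b, c, "cross_reference", "t"))
    return graph, a, b, c, d


class TestExpandTerms:
    def test_reachability_closure(self, chain_graph):
        graph, a, b, c, d = chain_graph
        # oracle: breadth-first reachability by hand on this 4-node fixture
        assert expand_terms(graph, {a}, {"alias_of", "cross_reference"}) == {a, b, c}

    def test_empty_seed(self, chain_graph):
        graph, *_ = chain_graph
        assert expand_terms(graph, set(), {"alias_of"}) == frozenset()

    def test_max_depth_zero_returns_seeds(self, chain_graph):
        graph, a, *_ = chain_graph
        assert expand_terms(graph, {a}, {"alias_of", "cross_reference"}, max_depth=0) == {a}

    def test_max_depth_one(self, chain_graph):
        graph, a, b, c, d = chain_graph
        assert expand_terms(graph, {a}, {"alias_of", "cross_reference"}, max_depth=1) == {a, b}

    def test_unknown_seed_is_referential_error(self, chain_graph):
        graph, *_ = chain_graph
        with pytest.raises(ReferentialIntegrityError):
            expand_terms(graph, {("nope", "x", "")}, {"alias_of"})

    def test_edge_type_restriction(self, chain_graph):
        graph, a, b, c, d = chain_graph
        assert expand_terms(graph, {a}, {"alias_of"}) == {a, b}

    def test_subclass_direction(self):
        graph = KnowledgeGraph()
        child = graph.add_term(OntologyTerm("s", "c", "child", "", "disease"))
        parent = graph.add_term(OntologyTerm("s", "p", "parent", "", "disease"))
        graph.add_edge(OntologyEdge(child, parent, "subclass_of", "s"))
        assert expand_terms(graph, {child}, {"subclass_of"}, subclass_direction="up") == {child, parent}
        assert expand_terms(graph, {parent}, {"subclass_of"}, subclass_direction="up") == {parent}
        assert expand_terms(graph, {parent}, {"subclass_of"}, subclass_direction="down") == {child, parent}
        assert expand_terms(graph, {child}, {"subclass_of"}, subclass_direction="both") == {child, parent}

    def test_cycles_tolerated(self):
        graph = KnowledgeGraph()
        a = graph.add_term(OntologyTerm("s", "a", "aa", "", "disease"))
        b = graph.add_term(OntologyTerm("s", "b", "bb", "", "disease"))
        graph.add_edge(OntologyEdge(a, b, "cross_reference", "s"))
        graph.add_edge(OntologyEdge(b, a, "cross_reference", "s"))
        assert expand_terms(graph, {a}, {"cross_reference"}) == {a, b}


def _random_graph(seed, n_nodes=60, n_edges=80):
    rng = random.Random(seed)
    graph = KnowledgeGraph()
    keys = [
        graph.add_term(OntologyTerm("s", f"n{i}", f"node {rng.randrange(10**6)} {i}", "", "therapy"))
        for i in range(n_nodes)
    ]
    types = ["alias_of", "cross_reference", "subclass_of", "element_of", "generalizes"]
    for _ in range(n_edges):
        a, b = rng.sample(keys, 2)
        graph.add_edge(OntologyEdge(a, b, rng.choice(types), "s"))
    return graph, keys


class TestExpandMonotonicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_edge_types_and_depth(self, seed):
        graph, keys = _random_graph(seed)
        rng = random.Random(seed + 1000)
        seeds = set(rng.sample(keys, 3))
        small = {"alias_of"}
        large = {"alias_of", "cross_reference", "element_of"}
        assert expand_terms(graph, seeds, small) <= expand_terms(graph, seeds, large)
        previous = frozenset(seeds)
        for depth in range(5):
            current = expand_terms(graph, seeds, large, max_depth=depth)
            assert previous <= current
            previous = current
        assert previous <= expand_terms(graph, seeds, large)


class TestCanonicalRepresentative:
    def test_lexicographic_rule(self, drug_graph):
        graph, a, b, c = drug_graph
        # "imatinib" < "imatinib mesylate"
        assert canonical_representative(graph, a) == a
        assert canonical_representative(graph, b) == a

    def test_isolated_term_maps_to_itself(self, drug_graph):
        graph, a, b, c = drug_graph
        assert canonical_representative(graph, c) == c

    @pytest.mark.parametrize("seed", range(8))
    def test_partition_equals_union_find(self, seed):
        graph, keys = _random_graph(seed, n_nodes=80, n_edges=100)
        edge_types = {"alias_of", "cross_reference"}
        partition = union_find_partition(graph, edge_types)
        reps = representative_map(graph, edge_types)
        for x in keys:
            for y in random.Random(seed).sample(keys, 10):
                same_component = y in partition[x]
                assert (reps[x] == reps[y]) == same_component
        # every member of a component shares the component's representative
        for key in keys:
            assert reps[key] in partition[key]


@pytest.fixture()
def coad_graph():
    graph = KnowledgeGraph()
    code = graph.add_term(OntologyTerm("oncotree", "COAD", "COAD", "", "disease"))
    detailed = graph.add_term(
        OntologyTerm("ncit", "C1", "colorectal adenocarcinoma", "", "disease")
    )
    broad = graph.add_term(OntologyTerm("ncit", "C2", "colorectal cancer", "", "disease"))
    graph.add_edge(OntologyEdge(code, detailed, "cross_reference", "oncotree"))
    graph.add_edge(OntologyEdge(detailed, broad, "subclass_of", "ncit"))
    graph.add_term(OntologyTerm("ncit", "C3", "lung cancer", "", "disease"))
    return graph, code, detailed, broad


class TestExpandDiagnosis:
    def test_collects_code_detailed_and_broad(self, coad_graph):
        graph, code, detailed, broad = coad_graph
        result = expand_diagnosis(graph, "COAD", "colorectal adenocarcinoma", "colorectal cancer")
        assert result == {code, detailed, broad}

    def test_single_resolvable_input_suffices(self, coad_graph):
        graph, code, detailed, broad = coad_graph
        assert expand_diagnosis(graph, "COAD", "", "") == {code, detailed, broad}

    def test_isolated_singleton(self, coad_graph):
        graph, *_ = coad_graph
        result = expand_diagnosis(graph, "", "", "lung cancer")
        assert {graph.term(k).name for k in result} == {"lung cancer"}

    def test_unresolvable_inputs_error(self, coad_graph):
        graph, *_ = coad_graph
        with pytest.raises(NoMatchError):
            expand_diagnosis(graph, "XXXX", "no such type", "nothing")
        with pytest.raises(NoMatchError):
            expand_diagnosis(graph, "", "", "")
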