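import itertools
import random

import pytest

from oncomatch.errors import ConfigurationError
from oncomatch.graph import KnowledgeGraph, OntologyEdge, OntologyTerm
from oncomatch.matching import (
    ALL_FILTERS,
    Match,
    apply_filters,
    map_evidence_to_amp_tier,
    match_all,
    match_direct,
    match_second_pass,
    parse_condition_name,
)
from oncomatch.simulate import random_matching_scenario
from oncomatch.variants import CopyVariant, Fusion, SmallMutation

from .oracles import oracle_apply_filters, oracle_match_all


KRAS_G12D = SmallMutation("KRAS", "p.G12D", "Missense_Mutation")


class TestConditionGrammar:
    @pytest.mark.parametrize(
        "name,kind",
        [
            ("KRAS:p.G12D", "small_mutation"),
            ("KRAS mutation", "small_mutation"),
            ("EGFR amplification", "copy"),
            ("CDKN2A deep deletion", "copy"),
            ("NRG1 increased expression", "expression"),
            ("PTEN reduced expression", "expression"),
            ("ATP1B1::NRG1 fusion", "fusion"),
            ("NRG1 fusion", "fusion"),
            ("oncogenic mutations in KRAS", "characterization"),
        ],
    )
    def test_kinds(self, name, kind):
        assert parse_condition_name(name).kind == kind

    def test_specific_vs_gene_level(self):
        specific = parse_condition_name("KRAS:p.G12D")
        assert specific.protein_change == "g12d"
        gene_level = parse_condition_name("KRAS mutation")
        assert gene_level.protein_change is None

    def test_non_variant_names_unparsed(self):
        assert parse_condition_name("colorectal cancer") is None


class TestMatchDirect:
    def test_position_specific_exact_identity(self, kras_graph):
        matches = match_direct(kras_graph, [KRAS_G12D])
        by_id = {m.statement: m for m in matches}
        assert "S1" in by_id
        assert by_id["S1"].non_specific is False
        assert by_id["S1"].variants == {KRAS_G12D}

    def test_gene_level_condition_flags_non_specific(self, kras_graph):
        matches = {m.statement: m for m in match_direct(kras_graph, [KRAS_G12D])}
        assert matches["S4"].non_specific is True

    def test_characterization_not_directly_satisfiable(self, kras_graph):
        assert "S2" not in {m.statement for m in match_direct(kras_graph, [KRAS_G12D])}

    def test_empty_variant_set(self, kras_graph):
        assert match_direct(kras_graph, []) == set()

    def test_protein_prefix_and_case_insensitive(self, kras_graph):
        variant = SmallMutation("kras", "G12D", "Missense_Mutation")
        assert "S1" in {m.statement for m in match_direct(kras_graph, [variant])}

    def test_alias_expanded_condition(self):
        graph = KnowledgeGraph()
        drug = graph.add_term(OntologyTerm("drugsa", "d", "drug", "", "therapy"))
        rel = graph.add_term(OntologyTerm("vocab", "r", "sensitivity", "", "relevance_term"))
        target = graph.add_term(OntologyTerm("vclass", "v1", "CDKN2A deep deletion", "", "variant_class"))
        alias = graph.add_term(OntologyTerm("vclass", "v2", "CDKN2A copy loss", "", "variant_class", True))
        graph.add_edge(OntologyEdge(alias, target, "alias_of", "vclass"))
        from oncomatch.graph import EvidenceItem, Statement

        graph.add_statement(
            Statement("S1", (alias,), drug, rel, (EvidenceItem("x"),), "civic", "therapeutic")
        )
        variant = CopyVariant("CDKN2A", -2, "deep_deletion")
        assert {m.statement for m in match_direct(graph, [variant])} == {"S1"}


class TestMatchSecondPass:
    def test_worked_example_single_hop(self, kras_graph):
        direct = match_direct(kras_graph, [KRAS_G12D])
        second = match_second_pass(kras_graph, direct, [KRAS_G12D])
        assert {m.statement for m in second} == {"S2"}
        (match,) = second
        assert match.via_statement == "S1"
        assert match.non_specific is True
        assert KRAS_G12D in match.variants

    def test_no_chaining_beyond_one_hop(self, kras_graph):
        # S3 builds on S2's conclusion; single-hop inference must not reach it
        matches = match_all(kras_graph, [KRAS_G12D])
        assert "S3" not in {m.statement for m in matches}

    def test_no_biological_matches_no_second_pass(self, kras_graph):
        fusion = Fusion("ATP1B1", "NRG1")
        assert match_second_pass(kras_graph, set(), [fusion]) == set()


class TestAmpTierMap:
    @pytest.mark.parametrize(
        "source,level",
        [
            ("civic", "A"),
            ("cgi", "FDA guidelines"),
            ("cgi", "NCCN guidelines"),
            ("cgi", "CPIC guidelines"),
            ("cgi", "NCCN/CAP guidelines"),
            ("cgi", "European Leukemianet guidelines"),
            ("oncokb", "1"),
            ("oncokb", "R1"),
            ("oncokb", "2A"),
        ],
    )
    def test_tier_one_pairs(self, source, level):
        assert map_evidence_to_amp_tier(source, level) == "tier_I"

    @pytest.mark.parametrize(
        "source,level",
        [
            ("civic", "B"),
            ("civic", "C"),
            ("oncokb", "3A"),
            ("oncokb", "4"),
            ("cgi", "Early trials"),
            ("cosmic", "anything"),  # no evidence scheme => never tier I
            ("cosmic", "1"),
            ("docm", "A"),
        ],
    )
    def test_unassigned_pairs(self, source, level):
        assert map_evidence_to_amp_tier(source, level) == "unassigned"


class TestApplyFilters:
    def test_empty_input(self, kras_graph):
        assert apply_filters(set(), ["Direct_Match"], kras_graph) == set()

    def test_direct_filter_removes_exactly_second_pass(self, kras_graph):
        matches = match_all(kras_graph, [KRAS_G12D])
        kept = apply_filters(matches, ["Direct_Match"], kras_graph)
        assert matches - kept == {m for m in matches if m.path_kind == "second_pass"}
        assert len(matches - kept) == 1

    def test_position_filter_drops_non_specific(self, kras_graph):
        matches = match_all(kras_graph, [KRAS_G12D])
        kept = apply_filters(matches, ["Position_Specific"], kras_graph)
        assert {m.statement for m in kept} == {"S1"}

    def test_unknown_filter_name(self, kras_graph):
        with pytest.raises(ConfigurationError):
            apply_filters(set(), ["Bogus"], kras_graph)

    def test_diagnosis_filter_requires_terms(self, kras_graph):
        matches = match_all(kras_graph, [KRAS_G12D])
        with pytest.raises(ConfigurationError):
            apply_filters(matches, ["Diagnosis_Match"], kras_graph)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_all_combinations_equal_oracle(self, seed):
        graph, variants = random_matching_scenario(seed, n_statements=60, n_variants=25)
        matches = match_all(graph, variants)
        for size in range(len(ALL_FILTERS) + 1):
            for names in itertools.combinations(ALL_FILTERS, size):
                kept = apply_filters(matches, names, graph, diagnosis_terms=frozenset())
                expected = oracle_apply_filters(matches, names, graph)
                assert kept == expected

    @pytest.mark.parametrize("seed", [2, 3])
    def test_subset_idempotent_order_independent(self, seed):
        graph, variants = random_matching_scenario(seed, n_statements=60, n_variants=25)
        matches = match_all(graph, variants)
        rng = random.Random(seed)
        names = rng.sample(ALL_FILTERS, 3)
        kept = apply_filters(matches, names, graph, diagnosis_terms=frozenset())
        assert kept <= matches
        assert apply_filters(kept, names, graph, diagnosis_terms=frozenset()) == kept
        permuted = apply_filters(
            matches, list(reversed(names)), graph, diagnosis_terms=frozenset()
        )
        assert permuted == kept
        # sequential composition equals the conjunction
        sequential = matches
        for name in names:
            sequential = apply_filters(sequential, [name], graph, diagnosis_terms=frozenset())
        assert sequential == kept


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_engine_equals_brute_force(self, seed):
        graph, variants = random_matching_scenario(seed, n_statements=80, n_variants=30)
        assert match_all(graph, variants) == oracle_match_all(graph, variants)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_removing_a_variant_never_adds_matches(self, seed):
        graph, variants = random_matching_scenario(seed, n_statements=60, n_variants=20)
        full = {(m.statement, m.path_kind) for m in match_all(graph, variants)}
        rng = random.Random(seed)
        smaller = list(variants)
        smaller.pop(rng.randrange(len(smaller)))
        reduced = {(m.statement, m.path_kind) for m in match_all(graph, smaller)}
        assert reduced <= full

    def test_deterministic_for_fixed_inputs(self):
        graph, variants = random_matching_scenario(11, n_statements=50, n_variants=20)
        assert match_all(graph, variants) == match_all(graph, variants)
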