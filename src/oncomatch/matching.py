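"""Variant-to-statement matching and the five therapeutic-applicability filters.

Variant conditions are ``variant_class`` ontology terms whose names follow a
small fixed grammar (compared after :func:`~oncomatch.traversal.normalize_label`):

===============================  ============================================
``GENE:p.X``                     position-specific small mutation
``GENE mutation``                gene-level small mutation (non-specific)
``GENE deep deletion``           copy loss call
``GENE amplification``           copy gain call
``GENE increased expression``    expression outlier, high
``GENE reduced expression``      expression outlier, low
``GENE5::GENE3 fusion``          specific fusion pair (5' to 3')
``GENE fusion``                  any fusion involving the gene
``REL mutations in GENE``        functional characterization; satisfied only
                                 through second-pass inference
===============================  ============================================

A direct match requires every variant-type condition of a statement to be
satisfied by the sample's variants; non-variant conditions (diseases, ...) do
not block matching and are handled by the filters.  Second-pass matching is a
single inference hop: a directly matched statement with a biological
relevance and a gene/variant-class subject can stand in for a
characterization condition of another statement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import (
    Dict,
    FrozenSet,
    Iterable,
    List,
    Optional,
    Sequence,
    Set,
    Tuple,
)

from .errors import ConfigurationError
from .graph import KnowledgeGraph, Statement, TermKey
from .traversal import (
    DIAGNOSIS_EDGES,
    EQUIVALENCE_EDGES,
    expand_terms,
    normalize_label,
)
from .variants import (
    CopyVariant,
    ExpressionVariant,
    Fusion,
    SmallMutation,
    Variant,
    is_nonsynonymous,
)

PATH_DIRECT = "direct"
PATH_SECOND_PASS = "second_pass"

#: edge types over which a variant-class condition is expanded before parsing
CONDITION_EDGES = frozenset({"alias_of", "generalizes"})


@dataclass(frozen=True)
class Match:
    """A (variant set, statement) pair with its path kind and flags."""

    variants: FrozenSet[Variant]
    statement: str
    path_kind: str
    via_statement: Optional[str] = None
    non_specific: bool = False

    def __post_init__(self) -> None:
        if (self.path_kind == PATH_SECOND_PASS) != (self.via_statement is not None):
            raise ConfigurationError(
                "via_statement must be present exactly for second-pass matches"
            )
        if not self.variants:
            raise ConfigurationError("a match requires at least one variant")


# -- condition grammar -------------------------------------------------------


@dataclass(frozen=True)
class VariantCondition:
    """Parsed view of a variant-class condition name (all fields normalized)."""

    kind: str  # small_mutation | copy | expression | fusion | characterization
    gene: Optional[str] = None
    protein_change: Optional[str] = None  # None => gene-level
    direction: Optional[str] = None
    gene3: Optional[str] = None
    relevance: Optional[str] = None


_CHAR_RE = re.compile(r"^(?P<rel>.+?) mutations in (?P<gene>\S+)$")
_FUSION_PAIR_RE = re.compile(r"^(?P<g5>[^\s:]+)::(?P<g3>[^\s:]+) fusion$")
_FUSION_ANY_RE = re.compile(r"^(?P<gene>[^\s:]+) fusion$")
_COPY_RE = re.compile(r"^(?P<gene>[^\s:]+) (?P<dir>deep deletion|amplification)$")
_EXPR_RE = re.compile(r"^(?P<gene>[^\s:]+) (?P<dir>increased|reduced) expression$")
_MUT_GENE_RE = re.compile(r"^(?P<gene>[^\s:]+) mutation$")
_MUT_POS_RE = re.compile(r"^(?P<gene>[^\s:]+):(?P<hgvs>\S+)$")


def strip_protein_prefix(protein_change: str) -> str:
    text = normalize_label(protein_change)
    return text[2:] if text.startswith("p.") else text


def parse_condition_name(name: str) -> Optional[VariantCondition]:
    """Parse a condition term name; ``None`` when it is not a variant pattern."""
    text = normalize_label(name)
    m = _CHAR_RE.match(text)
    if m:
        return VariantCondition(
            "characterization", gene=m.group("gene"), relevance=m.group("rel")
        )
    m = _FUSION_PAIR_RE.match(text)
    if m:
        return VariantCondition("fusion", gene=m.group("g5"), gene3=m.group("g3"))
    m = _FUSION_ANY_RE.match(text)
    if m:
        return VariantCondition("fusion", gene=m.group("gene"))
    m = _COPY_RE.match(text)
    if m:
        return VariantCondition(
            "copy", gene=m.group("gene"), direction=m.group("dir").replace(" ", "_")
        )
    m = _EXPR_RE.match(text)
    if m:
        return VariantCondition(
            "expression", gene=m.group("gene"), direction=m.group("dir")
        )
    m = _MUT_GENE_RE.match(text)
    if m:
        return VariantCondition("small_mutation", gene=m.group("gene"))
    m = _MUT_POS_RE.match(text)
    if m:
        return VariantCondition(
            "small_mutation",
            gene=m.group("gene"),
            protein_change=strip_protein_prefix(m.group("hgvs")),
        )
    return None


def condition_alternatives(
    graph: KnowledgeGraph, key: TermKey
) -> Tuple[VariantCondition, ...]:
    """Parsed forms of a condition term and of everything reachable from it
    over variant-class alias/generalizes links."""
    expanded = expand_terms(graph, [key], CONDITION_EDGES)
    out: List[VariantCondition] = []
    for term_key in sorted(expanded):
        term = graph.term(term_key)
        if term.term_class != "variant_class":
            continue
        parsed = parse_condition_name(term.name)
        if parsed is not None and parsed not in out:
            out.append(parsed)
    return tuple(out)


def _satisfy(
    condition: VariantCondition, variants: Sequence[Variant]
) -> Tuple[Set[Variant], bool]:
    """Variants satisfying one parsed condition, and whether any of them did
    so through a gene-level (non-specific) small-mutation pattern."""
    hits: Set[Variant] = set()
    non_specific = False
    for variant in variants:
        if condition.kind == "small_mutation" and isinstance(variant, SmallMutation):
            if normalize_label(variant.gene) != condition.gene:
                continue
            if condition.protein_change is None:
                hits.add(variant)
                non_specific = True
            elif variant.protein_change is not None and strip_protein_prefix(
                variant.protein_change
            ) == condition.protein_change:
                hits.add(variant)
        elif condition.kind == "copy" and isinstance(variant, CopyVariant):
            if (
                normalize_label(variant.gene) == condition.gene
                and variant.category == condition.direction
            ):
                hits.add(variant)
        elif condition.kind == "expression" and isinstance(variant, ExpressionVariant):
            if (
                normalize_label(variant.gene) == condition.gene
                and variant.direction == condition.direction
            ):
                hits.add(variant)
        elif condition.kind == "fusion" and isinstance(variant, Fusion):
            g5 = normalize_label(variant.gene5)
            g3 = normalize_label(variant.gene3)
            if condition.gene3 is not None:
                if (g5, g3) == (condition.gene, condition.gene3):
                    hits.add(variant)
            elif condition.gene in (g5, g3):
                hits.add(variant)
    return hits, non_specific


def _variant_condition_keys(graph: KnowledgeGraph, stmt: Statement) -> List[TermKey]:
    return [
        key for key in stmt.conditions if graph.term(key).term_class == "variant_class"
    ]


# -- direct matching ---------------------------------------------------------


def match_direct(
    graph: KnowledgeGraph, variants: Sequence[Variant]
) -> Set[Match]:
    """Direct matches: statements all of whose variant-type conditions are
    satisfied by the sample's variants.

    Statements with no variant-type condition are never variant-matched (a
    match must name at least one variant).  Characterization conditions are
    not directly satisfiable; statements carrying one are reached only via
    :func:`match_second_pass`.
    """
    matches: Set[Match] = set()
    for stmt in graph.statements():
        condition_keys = _variant_condition_keys(graph, stmt)
        if not condition_keys:
            continue
        all_hits: Set[Variant] = set()
        non_specific = False
        satisfied = True
        for key in condition_keys:
            hits: Set[Variant] = set()
            flagged = False
            for alternative in condition_alternatives(graph, key):
                if alternative.kind == "characterization":
                    continue
                found, ns = _satisfy(alternative, variants)
                if found:
                    hits |= found
                    flagged = flagged or ns
            if not hits:
                satisfied = False
                break
            all_hits |= hits
            non_specific = non_specific or flagged
        if satisfied:
            matches.add(
                Match(frozenset(all_hits), stmt.statement_id, PATH_DIRECT, None, non_specific)
            )
    return matches


# -- second-pass matching ----------------------------------------------------


def match_second_pass(
    graph: KnowledgeGraph,
    direct_matches: Iterable[Match],
    variants: Sequence[Variant],
) -> Set[Match]:
    """One inference hop beyond the direct matches.

    A direct match whose statement carries a biological relevance and a
    gene/variant-class subject asserts a functional characterization
    (relevance, subject).  Statements with exactly one characterization
    condition naming that pair (names compared over alias/cross-reference
    closures) — and all other variant conditions satisfied directly — are
    emitted as second-pass matches via the functional statement.  No chaining:
    second-pass matches never seed further inference, and statements with more
    than one characterization condition are not inferred.
    """
    backers: List[Tuple[FrozenSet[str], FrozenSet[str], Match]] = []
    for match in direct_matches:
        stmt = graph.statement(match.statement)
        if stmt.relevance_category != "biological":
            continue
        subject = graph.term(stmt.subject)
        if subject.term_class not in ("gene", "variant_class"):
            continue
        relevance_names = frozenset(
            normalize_label(graph.term(k).name)
            for k in expand_terms(graph, [stmt.relevance], EQUIVALENCE_EDGES)
        )
        subject_names = frozenset(
            normalize_label(graph.term(k).name)
            for k in expand_terms(graph, [stmt.subject], EQUIVALENCE_EDGES)
        )
        backers.append((relevance_names, subject_names, match))

    out: Set[Match] = set()
    if not backers:
        return out
    for stmt in graph.statements():
        condition_keys = _variant_condition_keys(graph, stmt)
        if not condition_keys:
            continue
        direct_hits: Set[Variant] = set()
        non_specific = False
        feasible = True
        char_backers: List[List[Match]] = []
        for key in condition_keys:
            hits: Set[Variant] = set()
            flagged = False
            backing: List[Match] = []
            for alternative in condition_alternatives(graph, key):
                if alternative.kind == "characterization":
                    for rel_names, subj_names, backer in backers:
                        if (
                            alternative.relevance in rel_names
                            and alternative.gene in subj_names
                            and backer.statement != stmt.statement_id
                        ):
                            backing.append(backer)
                else:
                    found, ns = _satisfy(alternative, variants)
                    if found:
                        hits |= found
                        flagged = flagged or ns
            if hits:
                direct_hits |= hits
                non_specific = non_specific or flagged
            elif backing:
                char_backers.append(backing)
            else:
                feasible = False
                break
        if not feasible or len(char_backers) != 1:
            continue
        for backer in char_backers[0]:
            out.add(
                Match(
                    frozenset(direct_hits | set(backer.variants)),
                    stmt.statement_id,
                    PATH_SECOND_PASS,
                    backer.statement,
                    True,  # characterization conditions are gene-level by nature
                )
            )
    return out


def match_all(graph: KnowledgeGraph, variants: Sequence[Variant]) -> Set[Match]:
    """Direct plus second-pass matches for one sample."""
    direct = match_direct(graph, variants)
    return direct | match_second_pass(graph, direct, variants)


# -- AMP tier mapping --------------------------------------------------------

#: (source kb, evidence level) pairs assigned the highest tier; everything
#: else — including sources with no evidence scheme — is unassigned.
DEFAULT_TIER_I_MAP: Dict[str, FrozenSet[str]] = {
    "civic": frozenset({"a"}),
    "cgi": frozenset(
        {
            "fda guidelines",
            "nccn guidelines",
            "cpic guidelines",
            "nccn/cap guidelines",
            "european leukemianet guidelines",
        }
    ),
    "oncokb": frozenset({"1", "r1", "2a"}),
}

TIER_I = "tier_I"
TIER_UNASSIGNED = "unassigned"


def map_evidence_to_amp_tier(
    source_kb: str,
    level: str,
    tier_map: Optional[Dict[str, FrozenSet[str]]] = None,
) -> str:
    table = DEFAULT_TIER_I_MAP if tier_map is None else tier_map
    levels = table.get(normalize_label(source_kb))
    if levels is not None and normalize_label(level) in levels:
        return TIER_I
    return TIER_UNASSIGNED


def statement_is_tier_one(
    stmt: Statement, tier_map: Optional[Dict[str, FrozenSet[str]]] = None
) -> bool:
    for item in stmt.evidence:
        if item.source_level is None:
            continue
        source, level = item.source_level
        if map_evidence_to_amp_tier(source, level, tier_map) == TIER_I:
            return True
    return False


# -- filters -----------------------------------------------------------------

FILTER_AMP_TIER_I = "AMP_Tier_I"
FILTER_DIAGNOSIS = "Diagnosis_Match"
FILTER_POSITION = "Position_Specific"
FILTER_DIRECT = "Direct_Match"
FILTER_NON_SYNON = "Non_Synon"

ALL_FILTERS = (
    FILTER_AMP_TIER_I,
    FILTER_DIAGNOSIS,
    FILTER_POSITION,
    FILTER_DIRECT,
    FILTER_NON_SYNON,
)


def match_passes_filter(
    match: Match,
    filter_name: str,
    graph: KnowledgeGraph,
    diagnosis_terms: Optional[FrozenSet[TermKey]] = None,
    tier_map: Optional[Dict[str, FrozenSet[str]]] = None,
    synonymous_classes: Optional[FrozenSet[str]] = None,
) -> bool:
    """Evaluate one filter predicate on one match.

    ``Diagnosis_Match``: the statement's disease conditions, expanded over
    cross-reference/alias/subclass links, must intersect the sample's
    diagnosis terms; statements with no disease condition pass (a pan-cancer
    biomarker is not dropped).
    """
    stmt = graph.statement(match.statement)
    if filter_name == FILTER_AMP_TIER_I:
        return statement_is_tier_one(stmt, tier_map)
    if filter_name == FILTER_DIAGNOSIS:
        if diagnosis_terms is None:
            raise ConfigurationError(
                "Diagnosis_Match filter requires expanded diagnosis terms"
            )
        disease_keys = [
            key for key in stmt.conditions if graph.term(key).term_class == "disease"
        ]
        if not disease_keys:
            return True
        expanded = expand_terms(
            graph, disease_keys, DIAGNOSIS_EDGES, subclass_direction="both"
        )
        return bool(expanded & diagnosis_terms)
    if filter_name == FILTER_POSITION:
        return not match.non_specific
    if filter_name == FILTER_DIRECT:
        return match.path_kind != PATH_SECOND_PASS
    if filter_name == FILTER_NON_SYNON:
        syn = synonymous_classes
        mutations = [v for v in match.variants if isinstance(v, SmallMutation)]
        if syn is None:
            return all(is_nonsynonymous(m) for m in mutations)
        return all(is_nonsynonymous(m, syn) for m in mutations)
    raise ConfigurationError(f"unknown filter name: {filter_name!r}")


def apply_filters(
    matches: Iterable[Match],
    filters: Iterable[str],
    graph: KnowledgeGraph,
    diagnosis_terms: Optional[FrozenSet[TermKey]] = None,
    tier_map: Optional[Dict[str, FrozenSet[str]]] = None,
    synonymous_classes: Optional[FrozenSet[str]] = None,
) -> Set[Match]:
    """Subset of matches passing every selected filter (predicate intersection)."""
    selected = list(filters)
    for name in selected:
        if name not in ALL_FILTERS:
            raise ConfigurationError(f"unknown filter name: {name!r}")
    return {
        match
        for match in matches
        if all(
            match_passes_filter(
                match, name, graph, diagnosis_terms, tier_map, synonymous_classes
            )
            for name in selected
        )
    }
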