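"""In-memory graph knowledge base: ontology terms, edges and evidence statements.

The store is deliberately plain: dictionaries keyed by the provenance triple
``(source, sourceId, sourceIdVersion)`` plus secondary indexes (normalized
name, condition-term reverse index).  It is not a database; persistence is a
round-trippable trio of plain-text files (terms TSV, edges TSV, statements
JSON Lines) handled in :mod:`oncomatch.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Set, Tuple

from .errors import (
    InvariantError,
    NoMatchError,
    ProvenanceCollisionError,
    ReferentialIntegrityError,
)
from .traversal import normalize_label

#: reference to a term: (source, sourceId, sourceIdVersion)
TermKey = Tuple[str, str, str]

TERM_CLASSES = frozenset(
    {
        "disease",
        "therapy",
        "gene",
        "variant_class",
        "evidence_level",
        "relevance_term",
        "signature",
    }
)

EDGE_TYPES = frozenset(
    {"cross_reference", "subclass_of", "alias_of", "element_of", "generalizes"}
)

RELEVANCE_CATEGORIES = frozenset({"therapeutic", "diagnostic", "prognostic", "biological"})

#: default relevance-label -> category assignment, applied at load time.
#: The category attribute is external to the vocabulary itself, so unknown
#: labels fall back to whatever category the statement declares.
DEFAULT_RELEVANCE_CATEGORY_MAP: Dict[str, str] = {
    "sensitivity": "therapeutic",
    "response": "therapeutic",
    "resistance": "therapeutic",
    "no response": "therapeutic",
    "diagnostic indicator": "diagnostic",
    "favours diagnosis": "diagnostic",
    "favourable prognosis": "prognostic",
    "unfavourable prognosis": "prognostic",
    "oncogenic": "biological",
    "likely oncogenic": "biological",
    "tumour suppressive": "biological",
    "gain of function": "biological",
    "loss of function": "biological",
}


@dataclass(frozen=True)
class OntologyTerm:
    """A provenance-stamped vocabulary node.

    ``source_id_version`` defaults to the empty string; keys always compare
    with the version included.
    """

    source: str
    source_id: str
    name: str
    source_id_version: str = ""
    term_class: str = "disease"
    is_alias: bool = False

    def __post_init__(self) -> None:
        if not normalize_label(self.name):
            raise InvariantError("term name is empty after whitespace trimming")
        if self.term_class not in TERM_CLASSES:
            raise InvariantError(f"unknown term class: {self.term_class!r}")
        if not self.source or not self.source_id:
            raise InvariantError("source and sourceId must be non-empty")

    @property
    def key(self) -> TermKey:
        return (self.source, self.source_id, self.source_id_version)


@dataclass(frozen=True)
class OntologyEdge:
    """A directed link between two terms; the asserting ontology is recorded.

    ``alias_of`` and ``subclass_of`` point alias->primary / child->parent.
    """

    from_term: TermKey
    to_term: TermKey
    edge_type: str
    asserted_by: str = ""

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise InvariantError(f"unknown edge type: {self.edge_type!r}")
        if self.edge_type == "alias_of" and self.from_term == self.to_term:
            raise InvariantError("alias_of self-loop")


@dataclass(frozen=True)
class EvidenceItem:
    """A citation backing a statement, optionally carrying a source evidence level."""

    citation_id: str
    source_level: Optional[Tuple[str, str]] = None

    def __post_init__(self) -> None:
        if not self.citation_id:
            raise InvariantError("citationId must be non-empty")


@dataclass(frozen=True)
class Statement:
    """An evidence assertion: >=1 conditions, exactly one subject and relevance."""

    statement_id: str
    conditions: Tuple[TermKey, ...]
    subject: TermKey
    relevance: TermKey
    evidence: Tuple[EvidenceItem, ...]
    source_kb: str
    relevance_category: str

    def __post_init__(self) -> None:
        if len(self.conditions) == 0:
            raise InvariantError("statement requires at least one condition")
        if len(self.evidence) == 0:
            raise InvariantError("statement requires at least one evidence item")
        if self.relevance_category not in RELEVANCE_CATEGORIES:
            raise InvariantError(
                f"unknown relevance category: {self.relevance_category!r}"
            )
        # normalize condition ordering so equality/hash are set-like
        object.__setattr__(self, "conditions", tuple(sorted(set(self.conditions))))


@dataclass
class Violation:
    """One invariant violation found by :meth:`KnowledgeGraph.validate`."""

    kind: str
    detail: str


class KnowledgeGraph:
    """Terms, edges and statements with the indexes needed for matching."""

    def __init__(
        self, relevance_category_map: Optional[Dict[str, str]] = None
    ) -> None:
        self._terms: Dict[TermKey, OntologyTerm] = {}
        self._name_index: Dict[str, Set[TermKey]] = {}
        self._edges: List[OntologyEdge] = []
        self._adjacency: Dict[TermKey, List[OntologyEdge]] = {}
        self._statements: Dict[str, Statement] = {}
        self._condition_index: Dict[TermKey, Set[str]] = {}
        self.relevance_category_map = dict(
            DEFAULT_RELEVANCE_CATEGORY_MAP
            if relevance_category_map is None
            else relevance_category_map
        )

    # -- terms ---------------------------------------------------------------

    def add_term(self, term: OntologyTerm) -> TermKey:
        if term.key in self._terms:
            raise ProvenanceCollisionError(
                f"duplicate term key {term.key}: provenance collision"
            )
        self._terms[term.key] = term
        self._name_index.setdefault(normalize_label(term.name), set()).add(term.key)
        return term.key

    def term(self, key: TermKey) -> OntologyTerm:
        try:
            return self._terms[key]
        except KeyError:
            raise ReferentialIntegrityError(f"unknown term {key}") from None

    def has_term(self, key: TermKey) -> bool:
        return key in self._terms

    def terms(self) -> Iterator[OntologyTerm]:
        return iter(self._terms.values())

    def __len__(self) -> int:
        return len(self._terms)

    def find_terms_by_name(
        self, query: str, term_class: Optional[str] = None
    ) -> FrozenSet[TermKey]:
        """All terms whose normalized name equals the normalized query.

        The full ambiguity set is returned rather than an arbitrary pick;
        an empty result raises :class:`NoMatchError` so the caller can tell
        "no exact match" apart from success.
        """
        keys = self._name_index.get(normalize_label(query), set())
        if term_class is not None:
            keys = {k for k in keys if self._terms[k].term_class == term_class}
        if not keys:
            raise NoMatchError(
                f"no exact name match for {query!r}"
                + (f" (class {term_class})" if term_class else "")
            )
        return frozenset(keys)

    # -- edges ---------------------------------------------------------------

    def add_edge(self, edge: OntologyEdge) -> None:
        for endpoint in (edge.from_term, edge.to_term):
            if endpoint not in self._terms:
                raise ReferentialIntegrityError(
                    f"edge endpoint {endpoint} not in graph"
                )
        self._edges.append(edge)
        self._adjacency.setdefault(edge.from_term, []).append(edge)
        self._adjacency.setdefault(edge.to_term, []).append(edge)

    @property
    def edges(self) -> Tuple[OntologyEdge, ...]:
        return tuple(self._edges)

    def edges_of(self, key: TermKey) -> Tuple[OntologyEdge, ...]:
        return tuple(self._adjacency.get(key, ()))

    # -- statements ----------------------------------------------------------

    def add_statement(self, stmt: Statement) -> str:
        if stmt.statement_id in self._statements:
            raise ProvenanceCollisionError(
                f"duplicate statement id {stmt.statement_id!r}"
            )
        for key in (*stmt.conditions, stmt.subject, stmt.relevance):
            if key not in self._terms:
                raise ReferentialIntegrityError(
                    f"statement {stmt.statement_id} references unknown term {key}"
                )
        declared = self.relevance_category_map.get(
            normalize_label(self.term(stmt.relevance).name)
        )
        if declared is not None and declared != stmt.relevance_category:
            raise InvariantError(
                f"statement {stmt.statement_id}: relevance category "
                f"{stmt.relevance_category!r} disagrees with the term's "
                f"assigned category {declared!r}"
            )
        self._statements[stmt.statement_id] = stmt
        for key in stmt.conditions:
            self._condition_index.setdefault(key, set()).add(stmt.statement_id)
        return stmt.statement_id

    def statement(self, statement_id: str) -> Statement:
        try:
            return self._statements[statement_id]
        except KeyError:
            raise ReferentialIntegrityError(
                f"unknown statement {statement_id!r}"
            ) from None

    def statements(self) -> Iterator[Statement]:
        # deterministic iteration order
        for sid in sorted(self._statements):
            yield self._statements[sid]

    @property
    def n_statements(self) -> int:
        return len(self._statements)

    def statements_for_condition(self, key: TermKey) -> FrozenSet[str]:
        return frozenset(self._condition_index.get(key, set()))

    # -- validation ----------------------------------------------------------

    def validate(self) -> List[Violation]:
        """Every invariant violation currently present; empty iff consistent.

        Violations are data, not exceptions: defective graphs produced by a
        lenient loader (or test corruption) are reported in full.
        """
        out: List[Violation] = []
        for edge in self._edges:
            for endpoint in (edge.from_term, edge.to_term):
                if endpoint not in self._terms:
                    out.append(
                        Violation("dangling_edge", f"{edge.edge_type} -> {endpoint}")
                    )
            if edge.edge_type == "alias_of" and edge.from_term == edge.to_term:
                out.append(Violation("alias_self_loop", str(edge.from_term)))
            if edge.edge_type not in EDGE_TYPES:
                out.append(Violation("bad_edge_type", edge.edge_type))
        alias_out: Dict[TermKey, int] = {}
        for edge in self._edges:
            if edge.edge_type == "alias_of":
                alias_out[edge.from_term] = alias_out.get(edge.from_term, 0) + 1
        for key, term in self._terms.items():
            if term.is_alias and alias_out.get(key, 0) != 1:
                out.append(
                    Violation(
                        "alias_without_edge",
                        f"{key} has {alias_out.get(key, 0)} alias_of edges (want 1)",
                    )
                )
        for stmt in self._statements.values():
            for key in (*stmt.conditions, stmt.subject, stmt.relevance):
                if key not in self._terms:
                    out.append(
                        Violation(
                            "dangling_statement_ref",
                            f"{stmt.statement_id} -> {key}",
                        )
                    )
        for key, sids in self._condition_index.items():
            for sid in sids:
                stmt = self._statements.get(sid)
                if stmt is None or key not in stmt.conditions:
                    out.append(Violation("stale_condition_index", f"{key} -> {sid}"))
        return out
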