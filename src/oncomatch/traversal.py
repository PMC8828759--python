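"""Label normalization and redundancy resolution over the ontology graph.

Semi-redundant ontologies are reconciled purely through asserted links:
reachability closures (:func:`expand_terms`), deterministic component
representatives (:func:`canonical_representative`) and diagnosis expansion
(:func:`expand_diagnosis`).  No fuzzy string matching is performed.
"""

from __future__ import annotations

from collections import deque
from typing import TYPE_CHECKING, Dict, FrozenSet, Iterable, Optional, Set, Tuple

import networkx as nx

from .errors import NoMatchError, ReferentialIntegrityError

if TYPE_CHECKING:  # pragma: no cover - type-only import avoids a cycle
    from .graph import KnowledgeGraph, TermKey


#: edge sets used throughout: equivalence-ish links vs the subclass hierarchy
EQUIVALENCE_EDGES = frozenset({"alias_of", "cross_reference"})
DIAGNOSIS_EDGES = frozenset({"alias_of", "cross_reference", "subclass_of"})


def normalize_label(raw: str) -> str:
    """Strip leading/trailing whitespace and lowercase; nothing else."""
    return raw.strip().lower()


def expand_terms(
    graph: "KnowledgeGraph",
    seeds: Iterable["TermKey"],
    edge_types: Iterable[str],
    max_depth: Optional[int] = None,
    subclass_direction: str = "up",
) -> FrozenSet["TermKey"]:
    """Reachability closure of ``seeds`` over the selected edge types.

    ``alias_of``, ``cross_reference``, ``element_of`` and ``generalizes`` are
    traversed as undirected.  ``subclass_of`` follows ``subclass_direction``:
    ``"up"`` (child->parent, the default), ``"down"``, or ``"both"``.  Cycles
    are tolerated (visited-set BFS).  The result is always a superset of the
    seeds; ``max_depth=0`` returns the seeds unchanged.
    """
    if subclass_direction not in ("up", "down", "both"):
        raise ValueError(f"bad subclass_direction: {subclass_direction!r}")
    edge_types = frozenset(edge_types)
    seed_keys = list(seeds)
    for key in seed_keys:
        if not graph.has_term(key):
            raise ReferentialIntegrityError(f"unknown seed term {key}")

    visited: Set["TermKey"] = set(seed_keys)
    queue: deque = deque((key, 0) for key in seed_keys)
    while queue:
        key, depth = queue.popleft()
        if max_depth is not None and depth >= max_depth:
            continue
        for edge in graph.edges_of(key):
            if edge.edge_type not in edge_types:
                continue
            if edge.edge_type == "subclass_of":
                if subclass_direction == "up":
                    if edge.from_term != key:
                        continue
                    nxt = edge.to_term
                elif subclass_direction == "down":
                    if edge.to_term != key:
                        continue
                    nxt = edge.from_term
                else:
                    nxt = edge.to_term if edge.from_term == key else edge.from_term
            else:
                nxt = edge.to_term if edge.from_term == key else edge.from_term
            if nxt not in visited and graph.has_term(nxt):
                visited.add(nxt)
                queue.append((nxt, depth + 1))
    return frozenset(visited)


def _undirected_view(graph: "KnowledgeGraph", edge_types: FrozenSet[str]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(term.key for term in graph.terms())
    for edge in graph.edges:
        if edge.edge_type in edge_types and graph.has_term(edge.from_term) and graph.has_term(edge.to_term):
            g.add_edge(edge.from_term, edge.to_term)
    return g


def _representative(graph: "KnowledgeGraph", component: Iterable["TermKey"]) -> "TermKey":
    def sort_key(key: "TermKey"):
        term = graph.term(key)
        return (normalize_label(term.name), term.source, term.source_id, term.source_id_version)

    return min(component, key=sort_key)


def canonical_representative(
    graph: "KnowledgeGraph",
    term: "TermKey",
    edge_types: Iterable[str] = EQUIVALENCE_EDGES,
) -> "TermKey":
    """Deterministic representative of the term's connected component.

    The member with the lexicographically smallest
    ``(normalized name, source, sourceId)`` triple is chosen, so every member
    of a component maps to the same representative on every run and platform.
    """
    if not graph.has_term(term):
        raise ReferentialIntegrityError(f"unknown term {term}")
    component = expand_terms(
        graph, [term], frozenset(edge_types) | set(), subclass_direction="both"
    )
    return _representative(graph, component)


def representative_map(
    graph: "KnowledgeGraph",
    edge_types: Iterable[str] = EQUIVALENCE_EDGES,
    link_same_names: bool = False,
) -> Dict["TermKey", "TermKey"]:
    """Representative for every term at once (connected-components pass).

    With ``link_same_names`` terms sharing a normalized name are additionally
    placed in one component (exact name identity as an equivalence signal);
    this makes the induced merge a pure coarsening of name equality.
    """
    view = _undirected_view(graph, frozenset(edge_types))
    if link_same_names:
        by_name: Dict[str, "TermKey"] = {}
        for term in graph.terms():
            label = normalize_label(term.name)
            if label in by_name:
                view.add_edge(by_name[label], term.key)
            else:
                by_name[label] = term.key
    out: Dict["TermKey", "TermKey"] = {}
    for component in nx.connected_components(view):
        rep = _representative(graph, component)
        for key in component:
            out[key] = rep
    return out


def expand_diagnosis(
    graph: "KnowledgeGraph",
    oncotree_code: str,
    detailed_type: str,
    cancer_type: str,
    subclass_direction: str = "both",
) -> FrozenSet["TermKey"]:
    """Final set of diagnosis disease terms for a sample.

    Each non-empty input is resolved by exact normalized name match against
    disease terms, expanded over cross-reference/alias/subclass links, and the
    union returned.  Whether the subclass hierarchy is ascended, descended or
    both is configurable; the default collects both directions so a biomarker
    stated for a broader disease still reaches a subtype.  If none of the
    three inputs resolves, :class:`NoMatchError` is raised.
    """
    inputs = [s for s in (oncotree_code, detailed_type, cancer_type) if s and s.strip()]
    if not inputs:
        raise NoMatchError("all diagnosis inputs are empty")
    seeds: Set["TermKey"] = set()
    for text in inputs:
        try:
            seeds |= graph.find_terms_by_name(text, term_class="disease")
        except NoMatchError:
            continue
    if not seeds:
        raise NoMatchError(f"no disease term matches any of {inputs!r}")
    return expand_terms(
        graph, seeds, DIAGNOSIS_EDGES, subclass_direction=subclass_direction
    )
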