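"""Cross-source agreement of clinically informative conclusions.

A conclusion is the (relevance, subject) projection of a statement.  Raw keys
compare normalized display names; normalized keys compare canonical component
representatives over alias/cross-reference links, so content shared under
alternate representations (e.g. a drug and its salt-name alias) collapses to
one conclusion.  Drug-class membership (``element_of``) does not merge by
default: a drug and its class remain distinct conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from .graph import KnowledgeGraph, TermKey
from .traversal import EQUIVALENCE_EDGES, normalize_label, representative_map

#: categories considered clinically informative by default
DEFAULT_CATEGORIES = frozenset({"therapeutic", "diagnostic", "prognostic"})


@dataclass(frozen=True)
class Conclusion:
    relevance: TermKey
    subject: TermKey
    raw_key: Tuple[str, str]
    normalized_key: Tuple[TermKey, TermKey]


def extract_conclusions(
    graph: KnowledgeGraph,
    categories: FrozenSet[str] = DEFAULT_CATEGORIES,
    merge_element_of: bool = False,
) -> Dict[str, List[Conclusion]]:
    """Per-source-kb conclusions for statements in the selected categories."""
    edge_types = set(EQUIVALENCE_EDGES)
    if merge_element_of:
        edge_types.add("element_of")
    # same-name terms share a component so normalization can only merge raw
    # keys, never split them (normalized unique count <= raw unique count)
    reps = representative_map(graph, frozenset(edge_types), link_same_names=True)
    per_source: Dict[str, List[Conclusion]] = {}
    for stmt in graph.statements():
        if stmt.relevance_category not in categories:
            continue
        conclusion = Conclusion(
            relevance=stmt.relevance,
            subject=stmt.subject,
            raw_key=(
                normalize_label(graph.term(stmt.relevance).name),
                normalize_label(graph.term(stmt.subject).name),
            ),
            normalized_key=(reps[stmt.relevance], reps[stmt.subject]),
        )
        per_source.setdefault(stmt.source_kb, []).append(conclusion)
    return per_source


@dataclass
class ConcordanceSummary:
    raw_unique: int
    normalized_unique: int
    raw_shared_fraction: float
    normalized_shared_fraction: float
    per_source_raw_unique: Dict[str, int]
    per_source_normalized_unique: Dict[str, int]


def _summarize(per_source_keys: Dict[str, Set]) -> Tuple[int, float, Dict[str, int]]:
    all_keys: Set = set()
    for keys in per_source_keys.values():
        all_keys |= keys
    shared = {
        key
        for key in all_keys
        if sum(1 for keys in per_source_keys.values() if key in keys) > 1
    }
    fraction = len(shared) / len(all_keys) if all_keys else 0.0
    return (
        len(all_keys),
        fraction,
        {source: len(keys) for source, keys in per_source_keys.items()},
    )


def concordance_summary(
    per_source: Dict[str, List[Conclusion]]
) -> ConcordanceSummary:
    """Unique-conclusion totals, per-source counts and the fraction of unique
    conclusions present in more than one source, for raw and normalized keys."""
    raw = {src: {c.raw_key for c in cs} for src, cs in per_source.items()}
    norm = {src: {c.normalized_key for c in cs} for src, cs in per_source.items()}
    raw_total, raw_fraction, raw_counts = _summarize(raw)
    norm_total, norm_fraction, norm_counts = _summarize(norm)
    return ConcordanceSummary(
        raw_unique=raw_total,
        normalized_unique=norm_total,
        raw_shared_fraction=raw_fraction,
        normalized_shared_fraction=norm_fraction,
        per_source_raw_unique=raw_counts,
        per_source_normalized_unique=norm_counts,
    )
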