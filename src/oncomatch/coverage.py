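"""Coverage of a frequency-weighted external terminology list by ontology terms.

Registry-style records (one JSON object per line: ``trialId``, ``conditions``,
``interventions [{name, type}]``) are reduced to per-class term-frequency
tables, where the frequency of a term is the number of distinct trials using
it.  Coverage of a term set at a threshold is the fraction of terms at or
above that frequency whose normalized name has an exact match in the set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set

from .errors import NoMatchError
from .graph import KnowledgeGraph
from .traversal import normalize_label

logger = logging.getLogger(__name__)

#: intervention types counted as therapy terms
DRUG_INTERVENTION_TYPES = frozenset(
    {"drug", "radiation", "combination product", "dietary supplement"}
)


def build_term_sets(
    graph: KnowledgeGraph,
    resource: str,
    include_aliases: bool,
    term_class: Optional[str] = None,
) -> FrozenSet[str]:
    """Normalized names of a resource's terms.

    The primary set (``include_aliases=False``) holds only preferred,
    non-alias records; the full ("+") set adds alias/synonym/product names.
    """
    names: Set[str] = set()
    found = False
    for term in graph.terms():
        if term.source != resource:
            continue
        found = True
        if term_class is not None and term.term_class != term_class:
            continue
        if term.is_alias and not include_aliases:
            continue
        names.add(normalize_label(term.name))
    if not found:
        raise NoMatchError(f"no terms from resource {resource!r} in the graph")
    return frozenset(names)


@dataclass
class TrialTermTables:
    """Distinct-trial frequency per normalized term, split by class."""

    therapy: Dict[str, int] = field(default_factory=dict)
    disease: Dict[str, int] = field(default_factory=dict)
    skipped_records: int = 0

    def table(self, term_class: str) -> Dict[str, int]:
        if term_class == "therapy":
            return self.therapy
        if term_class == "disease":
            return self.disease
        raise KeyError(term_class)


def parse_trial_terms(
    records: Iterable[Mapping],
    drug_intervention_types: FrozenSet[str] = DRUG_INTERVENTION_TYPES,
) -> TrialTermTables:
    """Registry records -> term-frequency tables.

    Therapy terms come from interventions whose type is in the inclusion
    list; disease terms from the condition list.  Frequencies count distinct
    trials.  Malformed records are logged, skipped and counted.
    """
    therapy_trials: Dict[str, Set[str]] = {}
    disease_trials: Dict[str, Set[str]] = {}
    skipped = 0
    for index, record in enumerate(records):
        try:
            trial_id = str(record["trialId"])
            conditions = record["conditions"]
            interventions = record["interventions"]
            if not trial_id or not isinstance(conditions, list):
                raise ValueError("bad trialId/conditions")
            for name in conditions:
                label = normalize_label(str(name))
                if label:
                    disease_trials.setdefault(label, set()).add(trial_id)
            for item in interventions:
                kind = normalize_label(str(item["type"]))
                label = normalize_label(str(item["name"]))
                if label and kind in drug_intervention_types:
                    therapy_trials.setdefault(label, set()).add(trial_id)
        except (KeyError, TypeError, ValueError) as exc:
            logger.warning("skipping malformed registry record %d: %s", index, exc)
            skipped += 1
    return TrialTermTables(
        therapy={term: len(trials) for term, trials in therapy_trials.items()},
        disease={term: len(trials) for term, trials in disease_trials.items()},
        skipped_records=skipped,
    )


def compute_coverage(
    term_set: FrozenSet[str], freq_table: Mapping[str, int], min_freq: int = 1
) -> float:
    """Fraction of terms at frequency >= ``min_freq`` present in the term set;
    0/0 is defined as 0."""
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    eligible = [term for term, freq in freq_table.items() if freq >= min_freq]
    if not eligible:
        return 0.0
    matched = sum(1 for term in eligible if term in term_set)
    return matched / len(eligible)


def coverage_table(
    graph: KnowledgeGraph,
    tables: TrialTermTables,
    resources: Mapping[str, str],
    min_freqs: Iterable[int] = (1, 10, 100),
    include_aliases: bool = True,
) -> List[dict]:
    """Coverage rows for each resource (mapped to its term class), each
    threshold, and the all-resources union per class."""
    rows: List[dict] = []
    union_sets: Dict[str, Set[str]] = {"therapy": set(), "disease": set()}
    for resource, term_class in sorted(resources.items()):
        names = build_term_sets(graph, resource, include_aliases, term_class)
        union_sets[term_class] |= names
        for min_freq in min_freqs:
            rows.append(
                {
                    "resource": resource,
                    "term_class": term_class,
                    "min_freq": min_freq,
                    "aliases_included": include_aliases,
                    "coverage": compute_coverage(
                        names, tables.table(term_class), min_freq
                    ),
                }
            )
    for term_class, names in sorted(union_sets.items()):
        if not names:
            continue
        for min_freq in min_freqs:
            rows.append(
                {
                    "resource": "all",
                    "term_class": term_class,
                    "min_freq": min_freq,
                    "aliases_included": include_aliases,
                    "coverage": compute_coverage(
                        frozenset(names), tables.table(term_class), min_freq
                    ),
                }
            )
    return rows
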