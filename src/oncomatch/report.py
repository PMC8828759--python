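"""Per-sample structured reports and the cohort variant-type breakdown.

A report is a document, not a rendered page: sample identity, diagnosis
inputs, per-type variant counts, the knowledge-base matches with per-filter
pass flags, conclusion counts, and the exact subset of variant types that
contributed a therapeutic match.  Serialization is JSON with stable field
ordering and a lossless round-trip.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources as importlib_resources
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import FormatError
from .graph import KnowledgeGraph, TermKey
from .matching import (
    ALL_FILTERS,
    PATH_SECOND_PASS,
    Match,
    match_passes_filter,
)
from .traversal import representative_map
from .variants import (
    CopyVariant,
    ExpressionVariant,
    Fusion,
    SmallMutation,
    Variant,
    variant_type_tag,
)

VARIANT_TYPES = ("mut", "cnv", "exp", "fus")


@dataclass(frozen=True)
class Diagnosis:
    oncotree_code: str
    cancer_type_detailed: str
    cancer_type: str


@dataclass(frozen=True)
class MatchRecord:
    """One match as reported: statement details plus per-filter flags."""

    statement_id: str
    source_kb: str
    relevance: str
    subject: str
    relevance_category: str
    path_kind: str
    via_statement: Optional[str]
    non_specific: bool
    variant_types: Tuple[str, ...]
    variants: Tuple[Variant, ...]
    filter_flags: Tuple[Tuple[str, bool], ...]


@dataclass(frozen=True)
class SampleReport:
    sample_id: str
    diagnosis: Diagnosis
    variant_counts: Tuple[Tuple[str, int], ...]
    matches: Tuple[MatchRecord, ...]
    unique_conclusions: int
    therapeutic_conclusions: int
    variant_type_group: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not set(self.variant_type_group) <= set(VARIANT_TYPES):
            raise FormatError(f"bad variant type group {self.variant_type_group}")
        if self.unique_conclusions < self.therapeutic_conclusions:
            raise FormatError("therapeutic conclusions exceed unique conclusions")


def summarize_sample(
    sample_id: str,
    diagnosis: Diagnosis,
    matches: Iterable[Match],
    graph: KnowledgeGraph,
    variant_counts: Optional[Mapping[str, int]] = None,
    diagnosis_terms: Optional[FrozenSet[TermKey]] = None,
    include_second_pass_in_groups: bool = False,
) -> SampleReport:
    """Collate one sample's matches into a report.

    Unique conclusions count distinct normalized (relevance, subject) pairs
    over the matched statements; the therapeutic count restricts to the
    therapeutic category.  Second-pass matches are excluded from variant-type
    attribution by default (they may mix variant types).
    """
    reps = representative_map(graph, link_same_names=True)
    matches = sorted(
        matches, key=lambda m: (m.statement, m.path_kind, m.via_statement or "")
    )
    records: List[MatchRecord] = []
    conclusion_keys = set()
    therapeutic_keys = set()
    group: set = set()
    for match in matches:
        stmt = graph.statement(match.statement)
        key = (reps[stmt.relevance], reps[stmt.subject])
        conclusion_keys.add(key)
        if stmt.relevance_category == "therapeutic":
            therapeutic_keys.add(key)
            if include_second_pass_in_groups or match.path_kind != PATH_SECOND_PASS:
                group |= {variant_type_tag(v) for v in match.variants}
        flags = tuple(
            (
                name,
                match_passes_filter(
                    match,
                    name,
                    graph,
                    diagnosis_terms if diagnosis_terms is not None else frozenset(),
                ),
            )
            for name in ALL_FILTERS
        )
        variants = tuple(sorted(match.variants, key=_variant_sort_key))
        records.append(
            MatchRecord(
                statement_id=stmt.statement_id,
                source_kb=stmt.source_kb,
                relevance=graph.term(stmt.relevance).name,
                subject=graph.term(stmt.subject).name,
                relevance_category=stmt.relevance_category,
                path_kind=match.path_kind,
                via_statement=match.via_statement,
                non_specific=match.non_specific,
                variant_types=tuple(
                    sorted({variant_type_tag(v) for v in match.variants})
                ),
                variants=variants,
                filter_flags=flags,
            )
        )
    counts = dict(variant_counts or {})
    return SampleReport(
        sample_id=sample_id,
        diagnosis=diagnosis,
        variant_counts=tuple(sorted(counts.items())),
        matches=tuple(records),
        unique_conclusions=len(conclusion_keys),
        therapeutic_conclusions=len(therapeutic_keys),
        variant_type_group=tuple(sorted(group)),
    )


def variant_type_breakdown(
    reports: Sequence[SampleReport],
) -> Tuple[Dict[str, int], Dict[str, int]]:
    """Mutually exclusive group counts plus per-type marginal totals.

    Each sample with a non-empty ``variant_type_group`` lands in exactly one
    group (label: sorted types joined by ``+``); group counts therefore sum to
    the number of samples with at least one attributable therapeutic match.
    """
    groups: Dict[str, int] = {}
    marginals: Dict[str, int] = {t: 0 for t in VARIANT_TYPES}
    for report in reports:
        if not report.variant_type_group:
            continue
        label = "+".join(report.variant_type_group)
        groups[label] = groups.get(label, 0) + 1
        for tag in report.variant_type_group:
            marginals[tag] += 1
    return groups, marginals


# -- serialization -----------------------------------------------------------

_VARIANT_TAGS = {"mut": SmallMutation, "cnv": CopyVariant, "exp": ExpressionVariant, "fus": Fusion}


def _variant_sort_key(variant: Variant):
    return (variant_type_tag(variant), tuple(map(str, asdict(variant).values())))


def _variant_to_dict(variant: Variant) -> dict:
    payload = asdict(variant)
    payload["type"] = variant_type_tag(variant)
    return payload


def _variant_from_dict(payload: dict) -> Variant:
    payload = dict(payload)
    cls = _VARIANT_TAGS[payload.pop("type")]
    return cls(**payload)


def report_to_dict(report: SampleReport) -> dict:
    return {
        "sample_id": report.sample_id,
        "diagnosis": {
            "oncotree_code": report.diagnosis.oncotree_code,
            "cancer_type_detailed": report.diagnosis.cancer_type_detailed,
            "cancer_type": report.diagnosis.cancer_type,
        },
        "variant_counts": {k: v for k, v in report.variant_counts},
        "matches": [
            {
                "statement_id": m.statement_id,
                "source_kb": m.source_kb,
                "relevance": m.relevance,
                "subject": m.subject,
                "relevance_category": m.relevance_category,
                "path_kind": m.path_kind,
                "via_statement": m.via_statement,
                "non_specific": m.non_specific,
                "variant_types": list(m.variant_types),
                "variants": [_variant_to_dict(v) for v in m.variants],
                "filter_flags": {k: v for k, v in m.filter_flags},
            }
            for m in report.matches
        ],
        "unique_conclusions": report.unique_conclusions,
        "therapeutic_conclusions": report.therapeutic_conclusions,
        "variant_type_group": list(report.variant_type_group),
    }


def report_from_dict(payload: dict) -> SampleReport:
    validate_report_payload(payload)
    return SampleReport(
        sample_id=payload["sample_id"],
        diagnosis=Diagnosis(
            oncotree_code=payload["diagnosis"]["oncotree_code"],
            cancer_type_detailed=payload["diagnosis"]["cancer_type_detailed"],
            cancer_type=payload["diagnosis"]["cancer_type"],
        ),
        variant_counts=tuple(sorted(payload["variant_counts"].items())),
        matches=tuple(
            MatchRecord(
                statement_id=m["statement_id"],
                source_kb=m["source_kb"],
                relevance=m["relevance"],
                subject=m["subject"],
                relevance_category=m["relevance_category"],
                path_kind=m["path_kind"],
                via_statement=m["via_statement"],
                non_specific=m["non_specific"],
                variant_types=tuple(m["variant_types"]),
                variants=tuple(_variant_from_dict(v) for v in m["variants"]),
                filter_flags=tuple(m["filter_flags"].items()),
            )
            for m in payload["matches"]
        ),
        unique_conclusions=payload["unique_conclusions"],
        therapeutic_conclusions=payload["therapeutic_conclusions"],
        variant_type_group=tuple(payload["variant_type_group"]),
    )


def serialize_report(report: SampleReport) -> str:
    """Schema-checked JSON with stable field ordering; round-trips exactly."""
    payload = report_to_dict(report)
    validate_report_payload(payload)
    return json.dumps(payload, indent=2, ensure_ascii=False, sort_keys=False)


def parse_report(text: str) -> SampleReport:
    return report_from_dict(json.loads(text))


def load_report_schema() -> dict:
    with importlib_resources.files("oncomatch.schemas").joinpath(
        "sample_report.schema.json"
    ).open("r", encoding="utf-8") as handle:
        return json.load(handle)


def validate_report_payload(payload: dict, schema: Optional[dict] = None) -> None:
    """Structural check against the shipped schema (types, required fields,
    enums); raises :class:`FormatError` on the first violation."""
    if schema is None:
        schema = load_report_schema()
    _check(payload, schema, "$")


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def _check(value, schema: dict, path: str) -> None:
    types = schema.get("type")
    if types is not None:
        allowed = types if isinstance(types, list) else [types]
        if "null" in allowed and value is None:
            return
        expected = tuple(
            t for name in allowed if name != "null" for t in _as_tuple(_TYPES[name])
        )
        if not isinstance(value, expected) or (
            isinstance(value, bool) and bool not in expected
        ):
            raise FormatError(f"{path}: expected {allowed}, got {type(value).__name__}")
    if "enum" in schema and value not in schema["enum"]:
        raise FormatError(f"{path}: {value!r} not in {schema['enum']}")
    if isinstance(value, dict):
        for name in schema.get("required", []):
            if name not in value:
                raise FormatError(f"{path}: missing required field {name!r}")
        properties = schema.get("properties", {})
        for name, sub in properties.items():
            if name in value:
                _check(value[name], sub, f"{path}.{name}")
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            for name, item in value.items():
                if name not in properties:
                    _check(item, extra, f"{path}.{name}")
    if isinstance(value, list) and "items" in schema:
        for index, item in enumerate(value):
            _check(item, schema["items"], f"{path}[{index}]")


def _as_tuple(value):
    return value if isinstance(value, tuple) else (value,)
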