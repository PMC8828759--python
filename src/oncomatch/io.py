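"""Readers and writers for the plain-text dialects.

All tabular files are UTF-8, tab-separated with a header row; missing values
are blank fields.  Statements and registry records are JSON Lines.  Loading
is auditable: per-stage counts are logged and malformed lines are reported
with their line numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple, Union

from .errors import FormatError
from .graph import (
    EvidenceItem,
    KnowledgeGraph,
    OntologyEdge,
    OntologyTerm,
    Statement,
    TermKey,
)
from .matching import Match
from .variants import (
    CopyVariant,
    ExpressionVariant,
    Fusion,
    SmallMutation,
    Variant,
)

logger = logging.getLogger(__name__)

TERM_COLUMNS = ("source", "sourceId", "name", "sourceIdVersion", "termClass", "isAlias")
EDGE_COLUMNS = ("fromSource", "fromId", "fromVersion", "toSource", "toId", "toVersion", "edgeType", "assertedBy")
SAMPLE_COLUMNS = ("sampleId", "oncotreeCode", "cancerTypeDetailed", "cancerType")


@dataclass
class LoadReport:
    """What a lenient load saw: counts plus (line number, message) warnings."""

    terms: int = 0
    edges: int = 0
    statements: int = 0
    warnings: List[Tuple[int, str]] = field(default_factory=list)


# -- terms / edges / statements ---------------------------------------------


def write_terms(terms: Iterable[OntologyTerm], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(TERM_COLUMNS) + "\n")
        for term in terms:
            handle.write(
                "\t".join(
                    (
                        term.source,
                        term.source_id,
                        term.name,
                        term.source_id_version,
                        term.term_class,
                        "true" if term.is_alias else "false",
                    )
                )
                + "\n"
            )


def _term_from_fields(fields: Dict[str, str]) -> OntologyTerm:
    return OntologyTerm(
        source=fields["source"],
        source_id=fields["sourceId"],
        name=fields["name"],
        source_id_version=fields["sourceIdVersion"],
        term_class=fields["termClass"],
        is_alias=fields["isAlias"].lower() == "true",
    )


def read_terms(path: Union[str, Path]) -> Iterator[OntologyTerm]:
    for number, fields in _tsv_rows(path, TERM_COLUMNS, "terms file"):
        yield _term_from_fields(fields)


def write_edges(edges: Iterable[OntologyEdge], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(EDGE_COLUMNS) + "\n")
        for edge in edges:
            handle.write(
                "\t".join((*edge.from_term, *edge.to_term, edge.edge_type, edge.asserted_by))
                + "\n"
            )


def _edge_from_fields(fields: Dict[str, str]) -> OntologyEdge:
    return OntologyEdge(
        from_term=(fields["fromSource"], fields["fromId"], fields["fromVersion"]),
        to_term=(fields["toSource"], fields["toId"], fields["toVersion"]),
        edge_type=fields["edgeType"],
        asserted_by=fields["assertedBy"],
    )


def read_edges(path: Union[str, Path]) -> Iterator[OntologyEdge]:
    for number, fields in _tsv_rows(path, EDGE_COLUMNS, "edges file"):
        yield _edge_from_fields(fields)


def statement_to_dict(stmt: Statement) -> dict:
    return {
        "statementId": stmt.statement_id,
        "conditions": [list(key) for key in stmt.conditions],
        "subject": list(stmt.subject),
        "relevance": list(stmt.relevance),
        "evidence": [
            {
                "citationId": item.citation_id,
                "sourceLevel": list(item.source_level) if item.source_level else None,
            }
            for item in stmt.evidence
        ],
        "sourceKb": stmt.source_kb,
        "relevanceCategory": stmt.relevance_category,
    }


def statement_from_dict(payload: dict) -> Statement:
    return Statement(
        statement_id=payload["statementId"],
        conditions=tuple(tuple(key) for key in payload["conditions"]),
        subject=tuple(payload["subject"]),
        relevance=tuple(payload["relevance"]),
        evidence=tuple(
            EvidenceItem(
                citation_id=item["citationId"],
                source_level=tuple(item["sourceLevel"]) if item.get("sourceLevel") else None,
            )
            for item in payload["evidence"]
        ),
        source_kb=payload["sourceKb"],
        relevance_category=payload["relevanceCategory"],
    )


def write_statements(statements: Iterable[Statement], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for stmt in statements:
            handle.write(json.dumps(statement_to_dict(stmt), ensure_ascii=False) + "\n")


def _statement_lines(path: Union[str, Path]) -> Iterator[dict]:
    with open(path, "r", encoding="utf-8") as handle:
        for number, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"statements file line {number}: {exc}") from exc


def read_statements(path: Union[str, Path]) -> Iterator[Statement]:
    for payload in _statement_lines(path):
        try:
            yield statement_from_dict(payload)
        except KeyError as exc:
            raise FormatError(f"statements file: missing field {exc}") from exc


def load_graph(
    terms_path: Union[str, Path],
    edges_path: Optional[Union[str, Path]] = None,
    statements_path: Optional[Union[str, Path]] = None,
    strict: bool = True,
) -> Tuple[KnowledgeGraph, LoadReport]:
    """Assemble a graph from the on-disk trio.

    ``strict=False`` records per-line warnings instead of raising, so a
    partially defective bundle can still be loaded and then examined with
    :meth:`KnowledgeGraph.validate`.
    """
    graph = KnowledgeGraph()
    report = LoadReport()

    def _ingest(rows, build, add, counter_attr):
        for number, payload in rows:
            try:
                add(build(payload))
                setattr(report, counter_attr, getattr(report, counter_attr) + 1)
            except Exception as exc:
                if strict:
                    raise
                report.warnings.append((number, str(exc)))

    _ingest(
        enumerate(_tsv_rows(terms_path, TERM_COLUMNS, "terms file"), start=1),
        lambda pair: _term_from_fields(pair[1]),
        graph.add_term,
        "terms",
    )
    if edges_path is not None:
        _ingest(
            enumerate(_tsv_rows(edges_path, EDGE_COLUMNS, "edges file"), start=1),
            lambda pair: _edge_from_fields(pair[1]),
            graph.add_edge,
            "edges",
        )
    if statements_path is not None:
        _ingest(
            enumerate(_statement_lines(statements_path), start=1),
            statement_from_dict,
            graph.add_statement,
            "statements",
        )
    logger.info(
        "loaded graph: %d terms, %d edges, %d statements (%d warnings)",
        report.terms,
        report.edges,
        report.statements,
        len(report.warnings),
    )
    return graph, report


# -- cohort metadata ---------------------------------------------------------


def write_samples(rows: Iterable[Tuple[str, str, str, str]], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(SAMPLE_COLUMNS) + "\n")
        for row in rows:
            handle.write("\t".join(row) + "\n")


def read_samples(path: Union[str, Path]) -> List[Dict[str, str]]:
    out = []
    for number, fields in _tsv_rows(path, SAMPLE_COLUMNS, "samples file"):
        out.append(fields)
    return out


# -- registry records --------------------------------------------------------


def write_registry(records: Iterable[dict], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for record in records:
            handle.write(json.dumps(record, ensure_ascii=False) + "\n")


def read_registry(path: Union[str, Path]) -> Iterator[dict]:
    with open(path, "r", encoding="utf-8") as handle:
        for number, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield json.loads(line)
            except json.JSONDecodeError:
                logger.warning("registry line %d: not valid JSON, skipped", number)
                yield {"_malformed_line": number}


# -- match records -----------------------------------------------------------

_VARIANT_WRITERS = {
    SmallMutation: lambda v: {"type": "mut", "gene": v.gene, "protein_change": v.protein_change, "classification": v.classification},
    CopyVariant: lambda v: {"type": "cnv", "gene": v.gene, "raw_value": v.raw_value, "category": v.category},
    ExpressionVariant: lambda v: {"type": "exp", "gene": v.gene, "z_score": v.z_score, "percentile": v.percentile, "direction": v.direction},
    Fusion: lambda v: {"type": "fus", "gene5": v.gene5, "gene3": v.gene3},
}

_VARIANT_READERS = {
    "mut": lambda d: SmallMutation(d["gene"], d["protein_change"], d["classification"]),
    "cnv": lambda d: CopyVariant(d["gene"], d["raw_value"], d["category"]),
    "exp": lambda d: ExpressionVariant(d["gene"], d["z_score"], d["percentile"], d["direction"]),
    "fus": lambda d: Fusion(d["gene5"], d["gene3"]),
}


def variant_to_dict(variant: Variant) -> dict:
    return _VARIANT_WRITERS[type(variant)](variant)


def variant_from_dict(payload: dict) -> Variant:
    payload = dict(payload)
    return _VARIANT_READERS[payload.pop("type")](payload)


def match_to_dict(match: Match, sample_id: Optional[str] = None) -> dict:
    payload = {
        "statement": match.statement,
        "pathKind": match.path_kind,
        "viaStatement": match.via_statement,
        "nonSpecific": match.non_specific,
        "variants": sorted(
            (variant_to_dict(v) for v in match.variants),
            key=lambda d: json.dumps(d, sort_keys=True),
        ),
    }
    if sample_id is not None:
        payload["sampleId"] = sample_id
    return payload


def match_from_dict(payload: dict) -> Match:
    return Match(
        variants=frozenset(variant_from_dict(v) for v in payload["variants"]),
        statement=payload["statement"],
        path_kind=payload["pathKind"],
        via_statement=payload["viaStatement"],
        non_specific=payload["nonSpecific"],
    )


def write_matches(
    per_sample: Dict[str, Iterable[Match]], path: Union[str, Path]
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for sample_id in sorted(per_sample):
            for match in sorted(
                per_sample[sample_id],
                key=lambda m: (m.statement, m.path_kind, m.via_statement or ""),
            ):
                handle.write(
                    json.dumps(match_to_dict(match, sample_id), ensure_ascii=False)
                    + "\n"
                )


def read_matches(path: Union[str, Path]) -> Dict[str, List[Match]]:
    out: Dict[str, List[Match]] = {}
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            payload = json.loads(line)
            out.setdefault(payload["sampleId"], []).append(match_from_dict(payload))
    return out


# -- helpers -----------------------------------------------------------------


def _tsv_rows(
    path: Union[str, Path], columns: Tuple[str, ...], what: str
) -> Iterator[Tuple[int, Dict[str, str]]]:
    with open(path, "r", encoding="utf-8") as handle:
        header_line = handle.readline().rstrip("\n")
        header = header_line.split("\t") if header_line else []
        for column in columns:
            if column not in header:
                raise FormatError(f"{what}: missing required column {column!r}")
        index = {column: header.index(column) for column in columns}
        for number, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise FormatError(f"{what} line {number}: expected {len(header)} fields")
            yield number, {column: fields[index[column]] for column in columns}
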