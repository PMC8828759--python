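"""Cohort-level orchestration shared by the CLI, tests and scripts."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple, Union

from .config import Config
from .errors import NoMatchError
from .graph import KnowledgeGraph
from .matching import Match, apply_filters, match_all
from .report import Diagnosis, SampleReport, summarize_sample
from .traversal import expand_diagnosis
from .variants import (
    Variant,
    parse_copy_matrix,
    parse_expression_matrix,
    parse_fusions,
    parse_small_mutations,
    variant_type_tag,
)

logger = logging.getLogger(__name__)


def load_cohort_variants(
    maf: Optional[Union[str, Path]] = None,
    cna: Optional[Union[str, Path]] = None,
    expression: Optional[Union[str, Path]] = None,
    fusions: Optional[Union[str, Path]] = None,
    config: Optional[Config] = None,
) -> Dict[str, List[Variant]]:
    """Parse whichever variant files are given into per-sample variant lists."""
    config = config or Config()
    per_sample: Dict[str, List[Variant]] = {}

    def _merge(groups: Dict[str, list]) -> None:
        for sample, items in groups.items():
            per_sample.setdefault(sample, []).extend(items)

    if maf is not None:
        mutations, dropped = parse_small_mutations(maf)
        logger.info("small mutations: %d rows dropped", dropped)
        _merge(mutations)
    if cna is not None:
        _merge(
            parse_copy_matrix(
                cna,
                config.copy_deletion_threshold,
                config.copy_amplification_threshold,
            )
        )
    if expression is not None:
        _merge(
            parse_expression_matrix(
                expression,
                z_low=config.expression_z_low,
                z_high=config.expression_z_high,
                percentile_low=config.expression_percentile_low,
                percentile_high=config.expression_percentile_high,
            )
        )
    if fusions is not None:
        fused, dropped = parse_fusions(fusions)
        logger.info("fusions: %d rows dropped", dropped)
        _merge(fused)
    return per_sample


def variant_counts(variants: Sequence[Variant]) -> Dict[str, int]:
    """Per-type counts of matchable variants (neutral calls are not counted)."""
    counts = {"mut": 0, "cnv": 0, "exp": 0, "fus": 0}
    for variant in variants:
        tag = variant_type_tag(variant)
        if tag == "cnv" and getattr(variant, "category", "") == "neutral":
            continue
        if tag == "exp" and getattr(variant, "direction", "") == "none":
            continue
        counts[tag] += 1
    return counts


def diagnosis_terms_for(
    graph: KnowledgeGraph, sample_meta: Dict[str, str]
) -> FrozenSet:
    try:
        return expand_diagnosis(
            graph,
            sample_meta.get("oncotreeCode", ""),
            sample_meta.get("cancerTypeDetailed", ""),
            sample_meta.get("cancerType", ""),
        )
    except NoMatchError:
        return frozenset()


def run_cohort(
    graph: KnowledgeGraph,
    sample_metadata: Sequence[Dict[str, str]],
    per_sample_variants: Dict[str, List[Variant]],
    config: Optional[Config] = None,
) -> Tuple[Dict[str, Set[Match]], Dict[str, SampleReport]]:
    """Match every sample, apply the configured filters, and build reports."""
    config = config or Config()
    matches_by_sample: Dict[str, Set[Match]] = {}
    reports: Dict[str, SampleReport] = {}
    for meta in sample_metadata:
        sample_id = meta["sampleId"]
        variants = per_sample_variants.get(sample_id, [])
        matches = match_all(graph, variants)
        diagnosis_terms = diagnosis_terms_for(graph, meta)
        if config.filters:
            matches = apply_filters(
                matches,
                config.filters,
                graph,
                diagnosis_terms=diagnosis_terms,
                tier_map=config.tier_one_map,
                synonymous_classes=config.synonymous_classes,
            )
        matches_by_sample[sample_id] = matches
        reports[sample_id] = summarize_sample(
            sample_id,
            Diagnosis(
                meta.get("oncotreeCode", ""),
                meta.get("cancerTypeDetailed", ""),
                meta.get("cancerType", ""),
            ),
            matches,
            graph,
            variant_counts=variant_counts(variants),
            diagnosis_terms=diagnosis_terms,
        )
        logger.info("sample %s: %d matches", sample_id, len(matches))
    return matches_by_sample, reports
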