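"""Seeded synthetic fixtures: ontologies, knowledge base, cohort, registry.

The generator stands in for external knowledge-base / cohort / registry
downloads.  Every truth it plants is derived *constructively* — each
statement's variant conditions use genes private to that statement, so the
expected match set, conclusion counts, variant-type breakdown and coverage
table can be written into the manifest without ever running the matching
engine.  Generation is a pure function of ``(seed, sizes)``.

Expression outliers are rank-based, so the number of samples sharing a
planted outlier on one gene is capped at what keeps the tied average-rank
percentile inside the 2.5/97.5 thresholds for the cohort size.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from . import io as om_io
from .errors import ConfigurationError
from .graph import (
    EvidenceItem,
    KnowledgeGraph,
    OntologyEdge,
    OntologyTerm,
    Statement,
    TermKey,
)
from .traversal import normalize_label

SOURCE_KBS = ("civic", "oncokb", "cosmic")
_KB_LEVELS = {
    "civic": ("A", "B", "C"),
    "oncokb": ("1", "R1", "2A", "3A", "4"),
    "cosmic": (),
}
_TIER_ONE_LEVELS = {"civic": {"a"}, "oncokb": {"1", "r1", "2a"}}

TEMPLATE_TAGS = ("mut", "mut", "cnv", "exp", "fus")  # template index -> type tag


@dataclass
class FixtureSizes:
    """Knobs for the synthetic bundle; all positive."""

    n_samples: int = 20
    n_statements: int = 40
    n_second_pass_pairs: int = 4
    n_decoy_genes: int = 8
    n_diseases: int = 5
    n_drugs: int = 12
    alias_fraction: float = 0.5
    n_registry_trials: int = 150
    n_registry_novel_terms: int = 12
    min_statements_per_sample: int = 1
    max_statements_per_sample: int = 5
    disease_condition_rate: float = 0.7
    silent_mutation_rate: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "n_samples",
            "n_statements",
            "n_diseases",
            "n_drugs",
            "n_registry_trials",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.min_statements_per_sample > self.max_statements_per_sample:
            raise ConfigurationError("min_statements_per_sample > max")
        if not 0.0 <= self.alias_fraction <= 1.0:
            raise ConfigurationError("alias_fraction must be in [0, 1]")


@dataclass
class FixtureBundle:
    graph: KnowledgeGraph
    samples: List[Dict[str, str]]
    maf_rows: List[Tuple[str, str, str, str]]
    cna_genes: List[str]
    cna_cells: Dict[Tuple[str, str], int]
    expression_genes: List[str]
    expression_cells: Dict[Tuple[str, str], float]
    fusion_rows: List[Tuple[str, str, str]]
    registry_records: List[dict]
    manifest: dict


def _expression_caps(n_samples: int) -> Tuple[int, int]:
    # tied average-rank percentile must stay inside 97.5 / 2.5 (inclusive)
    increased = n_samples // 20 + 1
    reduced = max(0, n_samples // 20 - 1)
    return increased, reduced


class _Builder:
    def __init__(self, seed: int, sizes: FixtureSizes) -> None:
        self.rng = random.Random(seed)
        self.sizes = sizes
        self.graph = KnowledgeGraph()
        self.term_records: List[OntologyTerm] = []
        self.edge_records: List[OntologyEdge] = []
        # bookkeeping for constructive truths
        self.relevance_terms: Dict[str, TermKey] = {}
        self.relevance_component: Dict[str, str] = {}
        self.disease_terms: Dict[int, Dict[str, TermKey]] = {}
        self.drug_terms: Dict[int, TermKey] = {}
        self.drug_alias_terms: Dict[int, TermKey] = {}
        self.subject_component: Dict[TermKey, str] = {}
        self.planted: Dict[str, dict] = {}  # statement id -> truth record
        self.vclass_counter = 0

    # -- term helpers --------------------------------------------------------

    def _add_term(self, term: OntologyTerm) -> TermKey:
        self.graph.add_term(term)
        self.term_records.append(term)
        return term.key

    def _add_edge(self, edge: OntologyEdge) -> None:
        self.graph.add_edge(edge)
        self.edge_records.append(edge)

    def _vclass(self, name: str) -> TermKey:
        self.vclass_counter += 1
        return self._add_term(
            OntologyTerm(
                source="vclass",
                source_id=f"vc{self.vclass_counter:05d}",
                name=name,
                term_class="variant_class",
            )
        )

    # -- vocabulary ----------------------------------------------------------

    def build_vocabulary(self) -> None:
        categories = {
            "sensitivity": "therapeutic",
            "resistance": "therapeutic",
            "diagnostic indicator": "diagnostic",
            "unfavourable prognosis": "prognostic",
            "oncogenic": "biological",
        }
        for index, (name, category) in enumerate(sorted(categories.items())):
            key = self._add_term(
                OntologyTerm(
                    source="vocab",
                    source_id=f"rel{index}",
                    name=name,
                    term_class="relevance_term",
                )
            )
            self.relevance_terms[name] = key
            self.relevance_component[name] = name
        alias = self._add_term(
            OntologyTerm(
                source="vocab",
                source_id="rel9",
                name="likely oncogenic",
                term_class="relevance_term",
                is_alias=True,
            )
        )
        self._add_edge(
            OntologyEdge(alias, self.relevance_terms["oncogenic"], "alias_of", "vocab")
        )
        self.relevance_terms["likely oncogenic"] = alias
        self.relevance_component["likely oncogenic"] = "oncogenic"

        for d in range(self.sizes.n_diseases):
            code = self._add_term(
                OntologyTerm("oncotree", f"dx{d}", f"dx{d}", "", "disease")
            )
            detailed = self._add_term(
                OntologyTerm("ncit", f"C{1000 + d}", f"cancer type {d} detailed", "", "disease")
            )
            parent = self._add_term(
                OntologyTerm("ncit", f"C{2000 + d}", f"cancer type {d}", "", "disease")
            )
            self._add_edge(OntologyEdge(code, detailed, "cross_reference", "oncotree"))
            self._add_edge(OntologyEdge(detailed, parent, "subclass_of", "ncit"))
            self.disease_terms[d] = {"code": code, "detailed": detailed, "parent": parent}
            self.subject_component[detailed] = f"disease:{d}"
            self.subject_component[code] = f"disease:{d}"
            self.subject_component[parent] = f"disease:{d}:parent"

        for j in range(self.sizes.n_drugs):
            primary = self._add_term(
                OntologyTerm("drugsa", f"da{j}", f"drug{j:03d}", "", "therapy")
            )
            self.drug_terms[j] = primary
            self.subject_component[primary] = f"drug:{j}"
            if self.rng.random() < self.sizes.alias_fraction:
                alias = self._add_term(
                    OntologyTerm(
                        "drugsb",
                        f"db{j}",
                        f"drug{j:03d} mesylate",
                        "",
                        "therapy",
                        is_alias=True,
                    )
                )
                self._add_edge(OntologyEdge(alias, primary, "alias_of", "drugsb"))
                self.drug_alias_terms[j] = alias
                self.subject_component[alias] = f"drug:{j}"

    def _gene(self, name: str) -> TermKey:
        key = self._add_term(OntologyTerm("hgnc", name.lower(), name, "", "gene"))
        self.subject_component[key] = f"gene:{name}"
        return key

    # -- statements ----------------------------------------------------------

    def build_statements(self) -> None:
        sizes = self.sizes
        for i in range(sizes.n_statements):
            template = i % 5
            gene_name = f"GEN{i:04d}"
            self._gene(gene_name)
            kb = SOURCE_KBS[i % len(SOURCE_KBS)]

            if i % 10 == 7:
                relevance_name, category = "diagnostic indicator", "diagnostic"
            elif i % 10 == 8:
                relevance_name, category = "unfavourable prognosis", "prognostic"
            elif i % 2 == 0:
                relevance_name, category = "sensitivity", "therapeutic"
            else:
                relevance_name, category = "resistance", "therapeutic"

            disease_index: Optional[int] = None
            if category == "therapeutic":
                j = i % sizes.n_drugs
                use_alias = j in self.drug_alias_terms and (i // sizes.n_drugs) % 2 == 1
                subject = self.drug_alias_terms[j] if use_alias else self.drug_terms[j]
            else:
                disease_index = i % sizes.n_diseases
                subject = self.disease_terms[disease_index]["detailed"]

            protein_change = None
            partner = None
            if template == 0:
                protein_change = f"p.G{12 + (i % 50)}D"
                condition_name = f"{gene_name}:{protein_change}"
            elif template == 1:
                condition_name = f"{gene_name} mutation"
            elif template == 2:
                direction = "deep deletion" if i % 10 < 5 else "amplification"
                condition_name = f"{gene_name} {direction}"
            elif template == 3:
                _, reduced_cap = _expression_caps(sizes.n_samples)
                direction = "reduced" if (reduced_cap > 0 and i % 10 >= 5) else "increased"
                condition_name = f"{gene_name} {direction} expression"
            else:
                partner = f"PRT{i:04d}"
                self._gene(partner)
                condition_name = f"{gene_name}::{partner} fusion"

            conditions = [self._vclass(condition_name)]
            if self.rng.random() < sizes.disease_condition_rate:
                if disease_index is None:
                    disease_index = self.rng.randrange(sizes.n_diseases)
                conditions.append(self.disease_terms[disease_index]["detailed"])

            statement_id = f"S{i:04d}"
            self._emit(
                statement_id,
                conditions,
                subject,
                relevance_name,
                category,
                kb,
                truth={
                    "template": template,
                    "type_tag": TEMPLATE_TAGS[template],
                    "gene": gene_name,
                    "partner": partner,
                    "protein_change": protein_change,
                    "condition_name": condition_name,
                    "disease": disease_index,
                    "pair_role": None,
                },
            )

        for p in range(sizes.n_second_pass_pairs):
            base = sizes.n_statements + 2 * p
            gene_name = f"GEN{base:04d}"
            self._gene(gene_name)
            functional_id = f"S{base:04d}"
            downstream_id = f"S{base + 1:04d}"
            relevance_name = "likely oncogenic" if p % 2 else "oncogenic"
            self._emit(
                functional_id,
                [self._vclass(f"{gene_name}:p.G12D")],
                ("hgnc", gene_name.lower(), ""),
                relevance_name,
                "biological",
                SOURCE_KBS[p % len(SOURCE_KBS)],
                truth={
                    "template": 0,
                    "type_tag": "mut",
                    "gene": gene_name,
                    "partner": None,
                    "protein_change": "p.G12D",
                    "condition_name": f"{gene_name}:p.G12D",
                    "disease": None,
                    "pair_role": ("functional", downstream_id),
                },
            )
            j = (base + 1) % sizes.n_drugs
            disease_index: Optional[int] = None
            conditions = [self._vclass(f"oncogenic mutations in {gene_name}")]
            if self.rng.random() < sizes.disease_condition_rate:
                disease_index = self.rng.randrange(sizes.n_diseases)
                conditions.append(self.disease_terms[disease_index]["detailed"])
            self._emit(
                downstream_id,
                conditions,
                self.drug_terms[j],
                "sensitivity" if p % 2 == 0 else "resistance",
                "therapeutic",
                SOURCE_KBS[(p + 1) % len(SOURCE_KBS)],
                truth={
                    "template": None,
                    "type_tag": "mut",
                    "gene": gene_name,
                    "partner": None,
                    "protein_change": None,
                    "condition_name": f"oncogenic mutations in {gene_name}",
                    "disease": disease_index,
                    "pair_role": ("downstream", functional_id),
                },
            )

    def _emit(
        self,
        statement_id: str,
        conditions: Sequence[TermKey],
        subject: TermKey,
        relevance_name: str,
        category: str,
        kb: str,
        truth: dict,
    ) -> None:
        levels = _KB_LEVELS[kb]
        level = self.rng.choice(levels) if levels else None
        evidence = EvidenceItem(
            citation_id=f"PMID:{100000 + len(self.planted)}",
            source_level=(kb, level) if level is not None else None,
        )
        stmt = Statement(
            statement_id=statement_id,
            conditions=tuple(conditions),
            subject=subject,
            relevance=self.relevance_terms[relevance_name],
            evidence=(evidence,),
            source_kb=kb,
            relevance_category=category,
        )
        self.graph.add_statement(stmt)
        tier_one = level is not None and normalize_label(level) in _TIER_ONE_LEVELS.get(
            kb, set()
        )
        truth.update(
            {
                "statement_id": statement_id,
                "relevance": relevance_name,
                "category": category,
                "source_kb": kb,
                "subject": list(subject),
                "tier_one": tier_one,
                "relevance_component": self.relevance_component[relevance_name],
                "subject_component": self.subject_component[subject],
            }
        )
        self.planted[statement_id] = truth

    # -- cohort --------------------------------------------------------------

    def build_cohort(self) -> Tuple[
        List[Dict[str, str]],
        List[Tuple[str, str, str, str]],
        Dict[Tuple[str, str], int],
        Dict[Tuple[str, str], float],
        List[Tuple[str, str, str]],
        List[dict],
    ]:
        sizes = self.sizes
        rng = self.rng
        increased_cap, reduced_cap = _expression_caps(sizes.n_samples)
        expression_plant_count: Dict[str, int] = {}

        pickable = [
            sid
            for sid, truth in self.planted.items()
            if truth["pair_role"] is None or truth["pair_role"][0] == "functional"
        ]
        pickable.sort()

        samples: List[Dict[str, str]] = []
        maf_rows: List[Tuple[str, str, str, str]] = []
        cna_cells: Dict[Tuple[str, str], int] = {}
        expression_cells: Dict[Tuple[str, str], float] = {}
        fusion_rows: List[Tuple[str, str, str]] = []
        sample_truths: List[dict] = []

        for s in range(sizes.n_samples):
            sample_id = f"SAMPLE{s:03d}"
            d = rng.randrange(sizes.n_diseases)
            samples.append(
                {
                    "sampleId": sample_id,
                    "oncotreeCode": f"dx{d}",
                    "cancerTypeDetailed": f"cancer type {d} detailed",
                    "cancerType": f"cancer type {d}",
                }
            )
            n_pick = rng.randint(
                sizes.min_statements_per_sample, sizes.max_statements_per_sample
            )
            picks = sorted(rng.sample(pickable, min(n_pick, len(pickable))))

            expected_matches: List[dict] = []
            conclusion_keys: Set[Tuple[str, str]] = set()
            therapeutic_keys: Set[Tuple[str, str]] = set()
            group: Set[str] = set()

            for sid in picks:
                truth = self.planted[sid]
                template = truth["template"]
                gene = truth["gene"]
                if template == 3:
                    cap = (
                        reduced_cap
                        if "reduced" in truth["condition_name"]
                        else increased_cap
                    )
                    if expression_plant_count.get(gene, 0) >= cap:
                        continue  # keep the rank-percentile guarantee
                    expression_plant_count[gene] = expression_plant_count.get(gene, 0) + 1

                non_specific = False
                if template == 0:
                    maf_rows.append(
                        (gene, truth["protein_change"], "Missense_Mutation", sample_id)
                    )
                elif template == 1:
                    non_specific = True
                    if rng.random() < sizes.silent_mutation_rate:
                        maf_rows.append((gene, f"p.R{s + 50}R", "Silent", sample_id))
                    else:
                        maf_rows.append(
                            (gene, f"p.R{s + 50}H", "Missense_Mutation", sample_id)
                        )
                elif template == 2:
                    value = -2 if "deep deletion" in truth["condition_name"] else 2
                    cna_cells[(gene, sample_id)] = value
                elif template == 3:
                    z = -4.0 if "reduced" in truth["condition_name"] else 4.0
                    expression_cells[(gene, sample_id)] = z
                else:
                    fusion_rows.append((gene, truth["partner"], sample_id))

                expected_matches.append(
                    {"statement": sid, "pathKind": "direct", "nonSpecific": non_specific}
                )
                key = (truth["relevance_component"], truth["subject_component"])
                conclusion_keys.add(key)
                if truth["category"] == "therapeutic":
                    therapeutic_keys.add(key)
                    group.add(truth["type_tag"])

                if truth["pair_role"] and truth["pair_role"][0] == "functional":
                    downstream = self.planted[truth["pair_role"][1]]
                    expected_matches.append(
                        {
                            "statement": downstream["statement_id"],
                            "pathKind": "second_pass",
                            "nonSpecific": True,
                        }
                    )
                    dkey = (
                        downstream["relevance_component"],
                        downstream["subject_component"],
                    )
                    conclusion_keys.add(dkey)
                    if downstream["category"] == "therapeutic":
                        therapeutic_keys.add(dkey)
                        # second-pass matches never contribute to the group

            # decoys: never touch statement genes
            for _ in range(rng.randint(0, 3)):
                decoy = f"DEC{rng.randrange(sizes.n_decoy_genes):04d}"
                maf_rows.append(
                    (decoy, f"p.A{rng.randint(1, 99)}V", "Missense_Mutation", sample_id)
                )
            if rng.random() < 0.3:
                maf_rows.append(("", "p.X1X", "Missense_Mutation", sample_id))
            if rng.random() < 0.3 and sizes.n_decoy_genes >= 2:
                a, b = rng.sample(range(sizes.n_decoy_genes), 2)
                fusion_rows.append((f"DEC{a:04d}", f"DEC{b:04d}", sample_id))

            sample_truths.append(
                {
                    "sampleId": sample_id,
                    "disease": d,
                    "expectedMatches": sorted(
                        expected_matches,
                        key=lambda m: (m["statement"], m["pathKind"]),
                    ),
                    "expectedUniqueConclusions": len(conclusion_keys),
                    "expectedTherapeuticConclusions": len(therapeutic_keys),
                    "expectedGroup": sorted(group),
                }
            )
        return samples, maf_rows, cna_cells, expression_cells, fusion_rows, sample_truths

    # -- matrices ------------------------------------------------------------

    def fill_matrices(
        self,
        samples: List[Dict[str, str]],
        cna_cells: Dict[Tuple[str, str], int],
        expression_cells: Dict[Tuple[str, str], float],
    ) -> Tuple[List[str], List[str]]:
        rng = self.rng
        sample_ids = [row["sampleId"] for row in samples]
        decoys = [f"DEC{k:04d}" for k in range(self.sizes.n_decoy_genes)]
        cna_genes = sorted(
            {
                truth["gene"]
                for truth in self.planted.values()
                if truth["template"] == 2
            }
        ) + decoys
        for gene in cna_genes:
            for sample_id in sample_ids:
                if (gene, sample_id) not in cna_cells:
                    cna_cells[(gene, sample_id)] = rng.choice([-1, 0, 0, 0, 1])
        expression_genes = sorted(
            {
                truth["gene"]
                for truth in self.planted.values()
                if truth["template"] == 3
            }
        ) + decoys
        for gene in expression_genes:
            for sample_id in sample_ids:
                if (gene, sample_id) not in expression_cells:
                    expression_cells[(gene, sample_id)] = round(
                        rng.uniform(-1.0, 1.0), 4
                    )
        return cna_genes, expression_genes

    # -- registry ------------------------------------------------------------

    def build_registry(self) -> Tuple[List[dict], dict]:
        sizes = self.sizes
        rng = self.rng
        n_trials = sizes.n_registry_trials

        primary_names: Dict[str, Set[str]] = {}
        full_names: Dict[str, Set[str]] = {}
        for term in self.term_records:
            full_names.setdefault(term.source, set()).add(normalize_label(term.name))
            if not term.is_alias:
                primary_names.setdefault(term.source, set()).add(
                    normalize_label(term.name)
                )

        def spectrum() -> int:
            roll = rng.random()
            if roll < 0.6:
                return rng.randint(1, 9)
            if roll < 0.9:
                return rng.randint(10, 99)
            return rng.randint(100, max(100, min(150, n_trials)))

        therapy_pool = sorted(full_names.get("drugsa", set()) | full_names.get("drugsb", set()))
        disease_pool = sorted(full_names.get("ncit", set()) | full_names.get("oncotree", set()))
        terms: List[Tuple[str, str, int]] = []
        for name in therapy_pool:
            terms.append((name, "therapy", spectrum()))
        for name in disease_pool:
            terms.append((name, "disease", spectrum()))
        for k in range(sizes.n_registry_novel_terms):
            terms.append((f"novel drug {k}", "therapy", spectrum()))
            terms.append((f"novel disease {k}", "disease", spectrum()))
        # behavioural interventions never count as therapy terms
        behavioural = [f"exercise programme {k}" for k in range(3)]

        drug_types = ["Drug", "Radiation", "Combination Product", "Dietary Supplement"]
        trials: List[dict] = [
            {"trialId": f"NCT{t:07d}", "conditions": [], "interventions": []}
            for t in range(n_trials)
        ]
        frequency: Dict[Tuple[str, str], int] = {}
        for index, (name, term_class, freq) in enumerate(terms):
            freq = min(freq, n_trials)
            frequency[(name, term_class)] = freq
            for t in rng.sample(range(n_trials), freq):
                if term_class == "disease":
                    trials[t]["conditions"].append(name)
                else:
                    trials[t]["interventions"].append(
                        {"name": name, "type": drug_types[index % len(drug_types)]}
                    )
        for name in behavioural:
            for t in rng.sample(range(n_trials), rng.randint(1, 5)):
                trials[t]["interventions"].append({"name": name, "type": "Behavioral"})

        resources = {
            "drugsa": "therapy",
            "drugsb": "therapy",
            "ncit": "disease",
            "oncotree": "disease",
        }
        expected: List[dict] = []
        for include_aliases in (False, True):
            union_sets: Dict[str, Set[str]] = {"therapy": set(), "disease": set()}
            for resource, term_class in sorted(resources.items()):
                names = (
                    full_names.get(resource, set())
                    if include_aliases
                    else primary_names.get(resource, set())
                )
                names = {
                    n
                    for n in names
                    if term_class
                    == (
                        "therapy"
                        if resource in ("drugsa", "drugsb")
                        else "disease"
                    )
                }
                union_sets[term_class] |= names
                for min_freq in (1, 10, 100):
                    eligible = [
                        name
                        for (name, cls), freq in frequency.items()
                        if cls == term_class and freq >= min_freq
                    ]
                    matched = sum(1 for name in eligible if name in names)
                    expected.append(
                        {
                            "resource": resource,
                            "term_class": term_class,
                            "min_freq": min_freq,
                            "aliases_included": include_aliases,
                            "coverage": matched / len(eligible) if eligible else 0.0,
                        }
                    )
            for term_class in ("disease", "therapy"):
                for min_freq in (1, 10, 100):
                    eligible = [
                        name
                        for (name, cls), freq in frequency.items()
                        if cls == term_class and freq >= min_freq
                    ]
                    matched = sum(
                        1 for name in eligible if name in union_sets[term_class]
                    )
                    expected.append(
                        {
                            "resource": "all",
                            "term_class": term_class,
                            "min_freq": min_freq,
                            "aliases_included": include_aliases,
                            "coverage": matched / len(eligible) if eligible else 0.0,
                        }
                    )
        return trials, {"resources": resources, "expected": expected}

    # -- concordance truth ---------------------------------------------------

    def concordance_truth(self) -> dict:
        informative = {"therapeutic", "diagnostic", "prognostic"}
        raw: Dict[str, Set[Tuple[str, str]]] = {}
        norm: Dict[str, Set[Tuple[str, str]]] = {}
        for truth in self.planted.values():
            if truth["category"] not in informative:
                continue
            subject_key = tuple(truth["subject"])
            subject_name = normalize_label(self.graph.term(subject_key).name)
            raw.setdefault(truth["source_kb"], set()).add(
                (normalize_label(truth["relevance"]), subject_name)
            )
            norm.setdefault(truth["source_kb"], set()).add(
                (truth["relevance_component"], truth["subject_component"])
            )

        def summarize(per_source: Dict[str, Set]) -> Tuple[int, float, Dict[str, int]]:
            everything: Set = set()
            for keys in per_source.values():
                everything |= keys
            shared = {
                key
                for key in everything
                if sum(1 for keys in per_source.values() if key in keys) > 1
            }
            return (
                len(everything),
                len(shared) / len(everything) if everything else 0.0,
                {source: len(keys) for source, keys in per_source.items()},
            )

        raw_total, raw_fraction, raw_counts = summarize(raw)
        norm_total, norm_fraction, norm_counts = summarize(norm)
        return {
            "raw_unique": raw_total,
            "normalized_unique": norm_total,
            "raw_shared_fraction": raw_fraction,
            "normalized_shared_fraction": norm_fraction,
            "per_source_raw_unique": raw_counts,
            "per_source_normalized_unique": norm_counts,
        }


def build_fixture(seed: int, sizes: Optional[FixtureSizes] = None) -> FixtureBundle:
    """Deterministic in-memory bundle plus its manifest of planted truths."""
    sizes = sizes or FixtureSizes()
    builder = _Builder(seed, sizes)
    builder.build_vocabulary()
    builder.build_statements()
    samples, maf_rows, cna_cells, expression_cells, fusion_rows, sample_truths = (
        builder.build_cohort()
    )
    cna_genes, expression_genes = builder.fill_matrices(
        samples, cna_cells, expression_cells
    )
    registry_records, coverage_truth = builder.build_registry()

    groups: Dict[str, int] = {}
    marginals: Dict[str, int] = {"mut": 0, "cnv": 0, "exp": 0, "fus": 0}
    for truth in sample_truths:
        if truth["expectedGroup"]:
            label = "+".join(truth["expectedGroup"])
            groups[label] = groups.get(label, 0) + 1
            for tag in truth["expectedGroup"]:
                marginals[tag] += 1

    manifest = {
        "seed": seed,
        "sizes": asdict(sizes),
        "counts": {
            "terms": len(builder.term_records),
            "edges": len(builder.edge_records),
            "statements": builder.graph.n_statements,
        },
        "samples": sample_truths,
        "breakdown": {"groups": groups, "marginals": marginals},
        "concordance": builder.concordance_truth(),
        "coverage": coverage_truth,
    }
    return FixtureBundle(
        graph=builder.graph,
        samples=samples,
        maf_rows=maf_rows,
        cna_genes=cna_genes,
        cna_cells=cna_cells,
        expression_genes=expression_genes,
        expression_cells=expression_cells,
        fusion_rows=fusion_rows,
        registry_records=registry_records,
        manifest=manifest,
    )


def write_fixture(bundle: FixtureBundle, out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Write the bundle as the plain-text file dialects; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "terms": out / "terms.tsv",
        "edges": out / "edges.tsv",
        "statements": out / "statements.jsonl",
        "maf": out / "maf.tsv",
        "cna": out / "cna.tsv",
        "expression": out / "expression.tsv",
        "fusions": out / "fusions.tsv",
        "samples": out / "samples.tsv",
        "registry": out / "registry.jsonl",
        "manifest": out / "manifest.json",
    }
    graph = bundle.graph
    om_io.write_terms(sorted(graph.terms(), key=lambda t: t.key), paths["terms"])
    om_io.write_edges(graph.edges, paths["edges"])
    om_io.write_statements(graph.statements(), paths["statements"])

    with open(paths["maf"], "w", encoding="utf-8") as handle:
        handle.write(
            "Hugo_Symbol\tHGVSp_Short\tVariant_Classification\tTumor_Sample_Barcode\n"
        )
        for row in bundle.maf_rows:
            handle.write("\t".join(row) + "\n")

    sample_ids = [row["sampleId"] for row in bundle.samples]
    with open(paths["cna"], "w", encoding="utf-8") as handle:
        handle.write("Hugo_Symbol\t" + "\t".join(sample_ids) + "\n")
        for gene in bundle.cna_genes:
            cells = [str(bundle.cna_cells[(gene, s)]) for s in sample_ids]
            handle.write(gene + "\t" + "\t".join(cells) + "\n")
    with open(paths["expression"], "w", encoding="utf-8") as handle:
        handle.write("Hugo_Symbol\t" + "\t".join(sample_ids) + "\n")
        for gene in bundle.expression_genes:
            cells = [repr(bundle.expression_cells[(gene, s)]) for s in sample_ids]
            handle.write(gene + "\t" + "\t".join(cells) + "\n")
    with open(paths["fusions"], "w", encoding="utf-8") as handle:
        handle.write("Hugo_Symbol\tFusion_Partner\tTumor_Sample_Barcode\n")
        for row in bundle.fusion_rows:
            handle.write("\t".join(row) + "\n")

    om_io.write_samples(
        [
            (
                row["sampleId"],
                row["oncotreeCode"],
                row["cancerTypeDetailed"],
                row["cancerType"],
            )
            for row in bundle.samples
        ],
        paths["samples"],
    )
    om_io.write_registry(bundle.registry_records, paths["registry"])
    with open(paths["manifest"], "w", encoding="utf-8") as handle:
        json.dump(bundle.manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return paths


def generate_fixture(
    seed: int, out_dir: Union[str, Path], sizes: Optional[FixtureSizes] = None
) -> Dict[str, Path]:
    return write_fixture(build_fixture(seed, sizes), out_dir)


# -- random (non-constructive) scenarios -------------------------------------


def random_matching_scenario(
    seed: int,
    n_statements: int = 100,
    n_variants: int = 40,
    n_genes: int = 12,
    n_diseases: int = 3,
):
    """A deliberately messy graph + variant set for oracle-equivalence tests.

    Unlike :func:`build_fixture`, statements share a small gene pool so
    incidental matches, multiple second-pass backers and alias-mediated
    condition hits all occur.  No truths are planted; correctness is checked
    against a brute-force oracle.
    """
    from .variants import (
        CopyVariant,
        ExpressionVariant,
        Fusion,
        SmallMutation,
        classify_copy_number,
        classify_expression,
    )

    rng = random.Random(seed)
    graph = KnowledgeGraph()

    relevance: Dict[str, TermKey] = {}
    for index, (name, is_alias) in enumerate(
        [
            ("sensitivity", False),
            ("resistance", False),
            ("unfavourable prognosis", False),
            ("oncogenic", False),
            ("likely oncogenic", True),
            ("loss of function", False),
        ]
    ):
        relevance[name] = graph.add_term(
            OntologyTerm("vocab", f"r{index}", name, "", "relevance_term", is_alias)
        )
    graph.add_edge(
        OntologyEdge(relevance["likely oncogenic"], relevance["oncogenic"], "alias_of", "vocab")
    )
    category_of = {
        "sensitivity": "therapeutic",
        "resistance": "therapeutic",
        "unfavourable prognosis": "prognostic",
        "oncogenic": "biological",
        "likely oncogenic": "biological",
        "loss of function": "biological",
    }

    genes = [f"GENE{g}" for g in range(n_genes)]
    gene_keys = {
        name: graph.add_term(OntologyTerm("hgnc", name.lower(), name, "", "gene"))
        for name in genes
    }
    drugs = [
        graph.add_term(OntologyTerm("drugsa", f"d{j}", f"drug{j}", "", "therapy"))
        for j in range(6)
    ]
    diseases = [
        graph.add_term(OntologyTerm("ncit", f"D{d}", f"disease {d}", "", "disease"))
        for d in range(n_diseases)
    ]

    protein_changes = ("p.G12D", "p.V600E", "p.T790M", "p.R132H")
    vc_count = 0

    def vclass(name: str) -> TermKey:
        nonlocal vc_count
        vc_count += 1
        return graph.add_term(
            OntologyTerm("vclass", f"v{vc_count}", name, "", "variant_class")
        )

    def random_condition() -> TermKey:
        gene = rng.choice(genes)
        kind = rng.randrange(9)
        if kind == 0:
            return vclass(f"{gene}:{rng.choice(protein_changes)}")
        if kind == 1:
            return vclass(f"{gene} mutation")
        if kind == 2:
            return vclass(f"{gene} deep deletion")
        if kind == 3:
            return vclass(f"{gene} amplification")
        if kind == 4:
            return vclass(f"{gene} increased expression")
        if kind == 5:
            return vclass(f"{gene} reduced expression")
        if kind == 6:
            return vclass(f"{gene}::{rng.choice(genes)} fusion")
        if kind == 7:
            return vclass(f"{gene} fusion")
        rel = rng.choice(["oncogenic", "likely oncogenic", "loss of function"])
        return vclass(f"{rel} mutations in {gene}")

    for i in range(n_statements):
        conditions = [random_condition() for _ in range(rng.randint(1, 2))]
        # occasionally alias a copy-loss spelling onto the first condition
        if rng.random() < 0.15:
            gene = rng.choice(genes)
            alias = vclass(f"{gene} copy loss")
            target = vclass(f"{gene} deep deletion")
            graph.add_edge(OntologyEdge(alias, target, "alias_of", "vclass"))
            conditions.append(alias)
        if rng.random() < 0.3:
            conditions.append(rng.choice(diseases))
        relevance_name = rng.choice(list(category_of))
        if category_of[relevance_name] == "biological" and rng.random() < 0.8:
            subject = gene_keys[rng.choice(genes)]
        else:
            subject = rng.choice(drugs)
        graph.add_statement(
            Statement(
                statement_id=f"R{i:04d}",
                conditions=tuple(conditions),
                subject=subject,
                relevance=relevance[relevance_name],
                evidence=(
                    EvidenceItem(
                        f"PMID:{i}",
                        (rng.choice(SOURCE_KBS), rng.choice(["A", "B", "1", "R1", "x"])),
                    ),
                ),
                source_kb=rng.choice(SOURCE_KBS),
                relevance_category=category_of[relevance_name],
            )
        )

    variants: List = []
    for _ in range(n_variants):
        gene = rng.choice(genes)
        kind = rng.randrange(5)
        if kind == 0:
            variants.append(
                SmallMutation(
                    gene,
                    rng.choice(protein_changes),
                    rng.choice(["Missense_Mutation", "Silent", "Nonsense_Mutation"]),
                )
            )
        elif kind == 1:
            variants.append(SmallMutation(gene, None, "Mutation"))
        elif kind == 2:
            value = rng.choice([-2, -1, 0, 1, 2])
            variants.append(CopyVariant(gene, value, classify_copy_number(value)))
        elif kind == 3:
            z = rng.choice([-4.0, -1.0, 0.5, 4.0])
            pct = rng.choice([1.0, 50.0, 99.0])
            variants.append(ExpressionVariant(gene, z, pct, classify_expression(z, pct)))
        else:
            variants.append(Fusion(gene, rng.choice(genes)))
    # dedupe: matching treats the variant set as a set
    unique: List = []
    seen = set()
    for variant in variants:
        if variant not in seen:
            seen.add(variant)
            unique.append(variant)
    return graph, unique
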