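"""Independent brute-force oracles.

These deliberately re-implement the semantics with different techniques than
the package (fixpoint closures instead of BFS, string slicing instead of
regexes, union-find instead of connected components) so agreement is
meaningful.  They read graph data only through the public accessors.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from oncomatch.matching import Match
from oncomatch.variants import CopyVariant, ExpressionVariant, Fusion, SmallMutation


def norm(text: str) -> str:
    return text.strip().lower()


# -- closure by fixpoint -----------------------------------------------------


def closure(graph, seeds, edge_types, subclass_direction="up", max_depth=None):
    """Reachability by repeated whole-edge-list passes (depth-tracked)."""
    depth = {key: 0 for key in seeds}
    changed = True
    while changed:
        changed = False
        for edge in graph.edges:
            if edge.edge_type not in edge_types:
                continue
            pairs = []
            if edge.edge_type == "subclass_of":
                if subclass_direction in ("up", "both"):
                    pairs.append((edge.from_term, edge.to_term))
                if subclass_direction in ("down", "both"):
                    pairs.append((edge.to_term, edge.from_term))
            else:
                pairs.append((edge.from_term, edge.to_term))
                pairs.append((edge.to_term, edge.from_term))
            for src, dst in pairs:
                if src in depth and graph.has_term(dst):
                    new_depth = depth[src] + 1
                    if max_depth is not None and new_depth > max_depth:
                        continue
                    if dst not in depth or new_depth < depth[dst]:
                        depth[dst] = new_depth
                        changed = True
    return frozenset(depth)


# -- union-find --------------------------------------------------------------


class UnionFind:
    def __init__(self, items):
        self.parent = {item: item for item in items}

    def find(self, item):
        while self.parent[item] != item:
            self.parent[item] = self.parent[self.parent[item]]
            item = self.parent[item]
        return item

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_partition(graph, edge_types) -> Dict:
    """term key -> frozenset of its component members."""
    uf = UnionFind([term.key for term in graph.terms()])
    for edge in graph.edges:
        if edge.edge_type in edge_types:
            uf.union(edge.from_term, edge.to_term)
    groups: Dict = {}
    for term in graph.terms():
        groups.setdefault(uf.find(term.key), set()).add(term.key)
    return {key: frozenset(groups[uf.find(key)]) for key in uf.parent}


# -- condition grammar (string slicing, not regex) ---------------------------


def parse_name(raw: str) -> Optional[tuple]:
    text = norm(raw)
    if " mutations in " in text:
        rel, _, gene = text.partition(" mutations in ")
        if rel and gene and " " not in gene:
            return ("char", rel, gene)
        return None
    if text.endswith(" fusion"):
        head = text[: -len(" fusion")]
        if "::" in head:
            g5, _, g3 = head.partition("::")
            if g5 and g3 and ":" not in g5 and ":" not in g3 and " " not in head:
                return ("fusion_pair", g5, g3)
            return None
        if head and " " not in head and ":" not in head:
            return ("fusion_any", head)
        return None
    for suffix, kind, extra in (
        (" deep deletion", "copy", "deep_deletion"),
        (" amplification", "copy", "amplification"),
        (" increased expression", "expr", "increased"),
        (" reduced expression", "expr", "reduced"),
        (" mutation", "mut_gene", None),
    ):
        if text.endswith(suffix):
            gene = text[: -len(suffix)]
            if gene and " " not in gene and ":" not in gene:
                return (kind, gene, extra)
            return None
    if ":" in text and " " not in text:
        gene, _, hgvs = text.partition(":")
        if gene and hgvs:
            if hgvs.startswith("p."):
                hgvs = hgvs[2:]
            return ("mut_pos", gene, hgvs)
    return None


def satisfied_by(parsed: tuple, variant) -> Tuple[bool, bool]:
    """(satisfied, via gene-level mutation pattern)"""
    kind = parsed[0]
    if kind == "mut_pos" and isinstance(variant, SmallMutation):
        if norm(variant.gene) != parsed[1] or variant.protein_change is None:
            return False, False
        change = norm(variant.protein_change)
        if change.startswith("p."):
            change = change[2:]
        return change == parsed[2], False
    if kind == "mut_gene" and isinstance(variant, SmallMutation):
        return norm(variant.gene) == parsed[1], norm(variant.gene) == parsed[1]
    if kind == "copy" and isinstance(variant, CopyVariant):
        return (
            norm(variant.gene) == parsed[1] and variant.category == parsed[2]
        ), False
    if kind == "expr" and isinstance(variant, ExpressionVariant):
        return (
            norm(variant.gene) == parsed[1] and variant.direction == parsed[2]
        ), False
    if kind == "fusion_pair" and isinstance(variant, Fusion):
        return (
            norm(variant.gene5) == parsed[1] and norm(variant.gene3) == parsed[2]
        ), False
    if kind == "fusion_any" and isinstance(variant, Fusion):
        return parsed[1] in (norm(variant.gene5), norm(variant.gene3)), False
    return False, False


def _condition_parses(graph, key) -> List[tuple]:
    expanded = closure(graph, [key], {"alias_of", "generalizes"}, "both")
    out = []
    for term_key in sorted(expanded):
        term = graph.term(term_key)
        if term.term_class != "variant_class":
            continue
        parsed = parse_name(term.name)
        if parsed is not None and parsed not in out:
            out.append(parsed)
    return out


def _evaluate_condition(graph, key, variants):
    """-> (hits, gene_level_flag, char_parses)"""
    hits: Set = set()
    flag = False
    chars: List[tuple] = []
    for parsed in _condition_parses(graph, key):
        if parsed[0] == "char":
            chars.append(parsed)
            continue
        for variant in variants:
            ok, gene_level = satisfied_by(parsed, variant)
            if ok:
                hits.add(variant)
                flag = flag or gene_level
    return hits, flag, chars


def oracle_match_direct(graph, variants) -> Set[Match]:
    out: Set[Match] = set()
    for stmt in graph.statements():
        keys = [
            k for k in stmt.conditions if graph.term(k).term_class == "variant_class"
        ]
        if not keys:
            continue
        everything: Set = set()
        non_specific = False
        ok = True
        for key in keys:
            hits, flag, _ = _evaluate_condition(graph, key, variants)
            if not hits:
                ok = False
                break
            everything |= hits
            non_specific = non_specific or flag
        if ok:
            out.add(
                Match(frozenset(everything), stmt.statement_id, "direct", None, non_specific)
            )
    return out


def oracle_match_second_pass(graph, direct, variants) -> Set[Match]:
    backers = []
    for match in direct:
        stmt = graph.statement(match.statement)
        if stmt.relevance_category != "biological":
            continue
        if graph.term(stmt.subject).term_class not in ("gene", "variant_class"):
            continue
        rel_names = {
            norm(graph.term(k).name)
            for k in closure(graph, [stmt.relevance], {"alias_of", "cross_reference"}, "both")
        }
        subj_names = {
            norm(graph.term(k).name)
            for k in closure(graph, [stmt.subject], {"alias_of", "cross_reference"}, "both")
        }
        backers.append((rel_names, subj_names, match))
    out: Set[Match] = set()
    for stmt in graph.statements():
        keys = [
            k for k in stmt.conditions if graph.term(k).term_class == "variant_class"
        ]
        if not keys:
            continue
        direct_hits: Set = set()
        non_specific = False
        feasible = True
        unsatisfied_char_conditions = []
        for key in keys:
            hits, flag, chars = _evaluate_condition(graph, key, variants)
            if hits:
                direct_hits |= hits
                non_specific = non_specific or flag
                continue
            found = [
                backer
                for parsed in chars
                for rel_names, subj_names, backer in backers
                if parsed[1] in rel_names
                and parsed[2] in subj_names
                and backer.statement != stmt.statement_id
            ]
            if found:
                unsatisfied_char_conditions.append(found)
            else:
                feasible = False
                break
        if not feasible or len(unsatisfied_char_conditions) != 1:
            continue
        for backer in unsatisfied_char_conditions[0]:
            out.add(
                Match(
                    frozenset(direct_hits | set(backer.variants)),
                    stmt.statement_id,
                    "second_pass",
                    backer.statement,
                    True,
                )
            )
    return out


def oracle_match_all(graph, variants) -> Set[Match]:
    direct = oracle_match_direct(graph, variants)
    return direct | oracle_match_second_pass(graph, direct, variants)


# -- filter predicates -------------------------------------------------------

ORACLE_TIER_ONE = {
    "civic": {"a"},
    "cgi": {
        "fda guidelines",
        "nccn guidelines",
        "cpic guidelines",
        "nccn/cap guidelines",
        "european leukemianet guidelines",
    },
    "oncokb": {"1", "r1", "2a"},
}


def oracle_filter(match: Match, name: str, graph, diagnosis_terms) -> bool:
    stmt = graph.statement(match.statement)
    if name == "AMP_Tier_I":
        for item in stmt.evidence:
            if item.source_level is not None:
                source, level = item.source_level
                if norm(level) in ORACLE_TIER_ONE.get(norm(source), set()):
                    return True
        return False
    if name == "Diagnosis_Match":
        disease_keys = [
            k for k in stmt.conditions if graph.term(k).term_class == "disease"
        ]
        if not disease_keys:
            return True
        expanded = closure(
            graph, disease_keys, {"alias_of", "cross_reference", "subclass_of"}, "both"
        )
        return bool(set(expanded) & set(diagnosis_terms))
    if name == "Position_Specific":
        return not match.non_specific
    if name == "Direct_Match":
        return match.path_kind != "second_pass"
    if name == "Non_Synon":
        for variant in match.variants:
            if isinstance(variant, SmallMutation):
                if variant.protein_change is None:
                    return False
                if norm(variant.classification) in {"silent", "synonymous"}:
                    return False
        return True
    raise ValueError(name)


def oracle_apply_filters(matches, names, graph, diagnosis_terms=frozenset()):
    return {
        match
        for match in matches
        if all(oracle_filter(match, name, graph, diagnosis_terms) for name in names)
    }
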