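"""Per-sample variant records and the cBioportal-style dialect parsers.

Four variant types are modelled: small mutations (MAF-like rows), discrete
copy calls (gene x sample integer matrix), expression outliers (gene x sample
z-score matrix) and fusions (pair list).  Classification thresholds are
inclusive: copy <= -2 is a deep deletion, >= +2 an amplification; expression
is an outlier only when the z-score AND the percentile both pass
(-2/+2 and 2.5/97.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Tuple, Union

import pandas as pd

from .errors import FormatError
from .traversal import normalize_label

COPY_CATEGORIES = ("deep_deletion", "amplification", "neutral")
EXPRESSION_DIRECTIONS = ("increased", "reduced", "none")

#: variant classifications treated as synonymous (configurable)
DEFAULT_SYNONYMOUS_CLASSES = frozenset({"silent", "synonymous"})


@dataclass(frozen=True)
class SmallMutation:
    """A small mutation; ``protein_change=None`` means gene-level/non-specific."""

    gene: str
    protein_change: Optional[str]
    classification: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise FormatError("small mutation requires a gene symbol")
        if self.protein_change is not None and not self.protein_change:
            raise FormatError("protein change, when present, must be non-empty")


@dataclass(frozen=True)
class CopyVariant:
    gene: str
    raw_value: float
    category: str

    def __post_init__(self) -> None:
        if self.category not in COPY_CATEGORIES:
            raise FormatError(f"bad copy category {self.category!r}")


@dataclass(frozen=True)
class ExpressionVariant:
    gene: str
    z_score: float
    percentile: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in EXPRESSION_DIRECTIONS:
            raise FormatError(f"bad expression direction {self.direction!r}")


@dataclass(frozen=True)
class Fusion:
    gene5: str
    gene3: str

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise FormatError("fusion requires both partner gene symbols")


Variant = Union[SmallMutation, CopyVariant, ExpressionVariant, Fusion]

#: short type tags used in reports and the variant-type breakdown
VARIANT_TYPE_TAGS: Dict[type, str] = {
    SmallMutation: "mut",
    CopyVariant: "cnv",
    ExpressionVariant: "exp",
    Fusion: "fus",
}


def variant_type_tag(variant: Variant) -> str:
    return VARIANT_TYPE_TAGS[type(variant)]


# -- classification ----------------------------------------------------------


def classify_copy_number(
    raw_value: float,
    deletion_threshold: float = -2.0,
    amplification_threshold: float = 2.0,
) -> str:
    """Deep deletion at <= -2, amplification at >= +2, else neutral (inclusive)."""
    if not math.isfinite(raw_value):
        raise FormatError(f"non-finite copy value: {raw_value!r}")
    if raw_value <= deletion_threshold:
        return "deep_deletion"
    if raw_value >= amplification_threshold:
        return "amplification"
    return "neutral"


def classify_expression(
    z_score: float,
    percentile: float,
    z_low: float = -2.0,
    z_high: float = 2.0,
    percentile_low: float = 2.5,
    percentile_high: float = 97.5,
) -> str:
    """Outlier direction from the AND of z-score and percentile thresholds."""
    if not (math.isfinite(z_score) and math.isfinite(percentile)):
        raise FormatError("non-finite expression inputs")
    if not 0.0 <= percentile <= 100.0:
        raise FormatError(f"percentile out of [0, 100]: {percentile!r}")
    if z_score >= z_high and percentile >= percentile_high:
        return "increased"
    if z_score <= z_low and percentile <= percentile_low:
        return "reduced"
    return "none"


def is_nonsynonymous(
    mutation: SmallMutation,
    synonymous_classes: FrozenSet[str] = DEFAULT_SYNONYMOUS_CLASSES,
) -> bool:
    """Protein-altering at the protein level: a protein change is present and
    the classification is not in the synonymous set."""
    if mutation.protein_change is None:
        return False
    return normalize_label(mutation.classification) not in synonymous_classes


# -- parsers -----------------------------------------------------------------

MAF_COLUMNS = (
    "Hugo_Symbol",
    "HGVSp_Short",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
)
FUSION_COLUMNS = ("Hugo_Symbol", "Fusion_Partner", "Tumor_Sample_Barcode")


def _require_columns(frame: pd.DataFrame, required: Tuple[str, ...], what: str) -> None:
    for column in required:
        if column not in frame.columns:
            raise FormatError(f"{what}: missing required column {column!r}")


def parse_small_mutations(
    source: Union[str, pd.DataFrame],
) -> Tuple[Dict[str, List[SmallMutation]], int]:
    """MAF-like table -> per-sample unique mutations plus the dropped-row count.

    Rows without a gene symbol (intergenic) are dropped; duplicate
    (sample, gene, proteinChange) rows are collapsed.  A blank protein-change
    field yields a gene-level record.
    """
    frame = _as_frame(source)
    _require_columns(frame, MAF_COLUMNS, "small-mutation table")
    per_sample: Dict[str, List[SmallMutation]] = {}
    seen: set = set()
    dropped = 0
    for row in frame.itertuples(index=False):
        gene = _clean(getattr(row, "Hugo_Symbol"))
        sample = _clean(getattr(row, "Tumor_Sample_Barcode"))
        if not gene or not sample:
            dropped += 1
            continue
        protein = _clean(getattr(row, "HGVSp_Short")) or None
        classification = _clean(getattr(row, "Variant_Classification"))
        dedup_key = (sample, gene, protein)
        if dedup_key in seen:
            dropped += 1
            continue
        seen.add(dedup_key)
        per_sample.setdefault(sample, []).append(
            SmallMutation(gene, protein, classification)
        )
    return per_sample, dropped


def parse_copy_matrix(
    source: Union[str, pd.DataFrame],
    deletion_threshold: float = -2.0,
    amplification_threshold: float = 2.0,
) -> Dict[str, List[CopyVariant]]:
    """Gene x sample integer matrix -> per-sample classified copy candidates."""
    frame = _as_frame(source)
    if "Hugo_Symbol" not in frame.columns:
        raise FormatError("copy matrix: missing required column 'Hugo_Symbol'")
    samples = [c for c in frame.columns if c != "Hugo_Symbol"]
    per_sample: Dict[str, List[CopyVariant]] = {str(s): [] for s in samples}
    genes = [_clean(g) for g in frame["Hugo_Symbol"]]
    for sample in samples:
        for gene, raw in zip(genes, frame[sample]):
            if not gene:
                continue
            try:
                value = float(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"copy matrix: non-numeric cell for {gene}/{sample}: {raw!r}"
                ) from None
            per_sample[str(sample)].append(
                CopyVariant(
                    gene,
                    value,
                    classify_copy_number(
                        value, deletion_threshold, amplification_threshold
                    ),
                )
            )
    return per_sample


def parse_expression_matrix(
    source: Union[str, pd.DataFrame],
    percentiles: Optional[pd.DataFrame] = None,
    z_low: float = -2.0,
    z_high: float = 2.0,
    percentile_low: float = 2.5,
    percentile_high: float = 97.5,
) -> Dict[str, List[ExpressionVariant]]:
    """Gene x sample z-score matrix -> per-sample expression calls.

    Percentiles default to the per-gene rank percentile of each sample within
    the cohort (average rank, scaled to 0..100); a pre-computed gene x sample
    percentile frame of identical shape may be supplied instead.
    """
    frame = _as_frame(source)
    if "Hugo_Symbol" not in frame.columns:
        raise FormatError("expression matrix: missing required column 'Hugo_Symbol'")
    values = frame.set_index("Hugo_Symbol").astype(float)
    if percentiles is None:
        pct = values.rank(axis=1, method="average", pct=True) * 100.0
    else:
        pct = percentiles.set_index("Hugo_Symbol").astype(float)
    if list(pct.columns) != list(values.columns):
        pct = pct[values.columns]
    per_sample: Dict[str, List[ExpressionVariant]] = {
        str(s): [] for s in values.columns
    }
    for i, gene in enumerate(values.index):
        for j, sample in enumerate(values.columns):
            z = values.iat[i, j]
            p = float(pct.iat[i, j])
            per_sample[str(sample)].append(
                ExpressionVariant(
                    str(gene),
                    float(z),
                    p,
                    classify_expression(
                        float(z), p, z_low, z_high, percentile_low, percentile_high
                    ),
                )
            )
    return per_sample


def parse_fusions(
    source: Union[str, pd.DataFrame],
) -> Tuple[Dict[str, List[Fusion]], int]:
    """Fusion pair list -> per-sample fusions plus the dropped-row count."""
    frame = _as_frame(source)
    _require_columns(frame, FUSION_COLUMNS, "fusion table")
    per_sample: Dict[str, List[Fusion]] = {}
    seen: set = set()
    dropped = 0
    for row in frame.itertuples(index=False):
        gene5 = _clean(getattr(row, "Hugo_Symbol"))
        gene3 = _clean(getattr(row, "Fusion_Partner"))
        sample = _clean(getattr(row, "Tumor_Sample_Barcode"))
        if not gene5 or not gene3 or not sample:
            dropped += 1
            continue
        dedup_key = (sample, gene5, gene3)
        if dedup_key in seen:
            dropped += 1
            continue
        seen.add(dedup_key)
        per_sample.setdefault(sample, []).append(Fusion(gene5, gene3))
    return per_sample, dropped


# -- helpers -----------------------------------------------------------------


def _as_frame(source: Union[str, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)


def _clean(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return str(value).strip()
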