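import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oncomatch.errors import FormatError
from oncomatch.variants import (
    CopyVariant,
    ExpressionVariant,
    Fusion,
    SmallMutation,
    classify_copy_number,
    classify_expression,
    is_nonsynonymous,
    parse_copy_matrix,
    parse_expression_matrix,
    parse_fusions,
    parse_small_mutations,
)


class TestClassifyCopyNumber:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (-3, "deep_deletion"),
            (-2, "deep_deletion"),  # boundary is inclusive
            (-1.999, "neutral"),
            (-1, "neutral"),
            (0, "neutral"),
            (1, "neutral"),
            (1.999, "neutral"),
            (2, "amplification"),  # boundary is inclusive
            (5, "amplification"),
        ],
    )
    def test_thresholds(self, value, expected):
        assert classify_copy_number(value) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(FormatError):
            classify_copy_number(float("nan"))

    @given(st.floats(allow_nan=False, allow_infinity=False, width=32))
    def test_total_on_finite_inputs(self, value):
        assert classify_copy_number(value) in {"deep_deletion", "amplification", "neutral"}


class TestClassifyExpression:
    @pytest.mark.parametrize(
        "z,pct,expected",
        [
            (2.5, 99.0, "increased"),
            (2.0, 97.5, "increased"),  # both boundaries inclusive
            (-2.4, 1.0, "reduced"),
            (-2.0, 2.5, "reduced"),
            (2.5, 50.0, "none"),  # z passes, percentile fails: AND rule
            (1.0, 99.9, "none"),  # percentile passes, z fails
            (-2.5, 50.0, "none"),
            (0.0, 50.0, "none"),
            (1.999, 97.5, "none"),
            (2.0, 97.499, "none"),
            (-2.0, 2.501, "none"),
            (-1.999, 2.5, "none"),
        ],
    )
    def test_and_combination(self, z, pct, expected):
        assert classify_expression(z, pct) == expected

    def test_percentile_out_of_range(self):
        with pytest.raises(FormatError):
            classify_expression(0.0, 101.0)
        with pytest.raises(FormatError):
            classify_expression(0.0, -0.1)


class TestIsNonsynonymous:
    def test_protein_altering(self):
        assert is_nonsynonymous(SmallMutation("KRAS", "p.G12D", "Missense_Mutation"))

    def test_silent_class(self):
        assert not is_nonsynonymous(SmallMutation("TP53", "p.R213R", "Silent"))

    def test_gene_level_record_is_not_protein_level(self):
        # a record with no protein change cannot pass a protein-level filter
        assert not is_nonsynonymous(SmallMutation("KRAS", None, "Missense_Mutation"))

    def test_configurable_synonymous_set(self):
        mutation = SmallMutation("X", "p.A1A", "Weird_Class")
        assert is_nonsynonymous(mutation)
        assert not is_nonsynonymous(mutation, frozenset({"weird_class"}))


def _maf(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol",
            "HGVSp_Short",
            "Variant_Classification",
            "Tumor_Sample_Barcode",
        ],
    )


class TestParseSmallMutations:
    def test_field_mapping(self):
        per_sample, dropped = parse_small_mutations(
            _maf([("KRAS", "p.G12D", "Missense_Mutation", "S1")])
        )
        assert dropped == 0
        assert per_sample == {
            "S1": [SmallMutation("KRAS", "p.G12D", "Missense_Mutation")]
        }

    def test_intergenic_rows_dropped(self):
        rows = [(f"G{i}", f"p.A{i}V", "Missense_Mutation", "S1") for i in range(8)]
        rows.insert(2, ("", "p.X1X", "IGR", "S1"))
        rows.insert(5, ("", "", "IGR", "S1"))
        per_sample, dropped = parse_small_mutations(_maf(rows))
        # oracle: 10 rows, 2 lack a gene symbol => 8 records
        assert dropped == 2
        assert sum(len(v) for v in per_sample.values()) == 8

    def test_blank_protein_change_is_gene_level(self):
        per_sample, _ = parse_small_mutations(_maf([("KRAS", "", "Mutation", "S1")]))
        assert per_sample["S1"][0].protein_change is None

    def test_duplicates_collapsed(self):
        rows = [("KRAS", "p.G12D", "Missense_Mutation", "S1")] * 3
        per_sample, dropped = parse_small_mutations(_maf(rows))
        assert len(per_sample["S1"]) == 1 and dropped == 2

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("Hugo_Symbol\tHGVSp_Short\nKRAS\tp.G12D\n")
        with pytest.raises(FormatError, match="Variant_Classification"):
            parse_small_mutations(str(path))

    def test_output_never_exceeds_input(self):
        rows = [("A", "p.G1D", "Missense_Mutation", "S1"), ("", "", "IGR", "S1")]
        per_sample, dropped = parse_small_mutations(_maf(rows))
        total = sum(len(v) for v in per_sample.values())
        assert total + dropped == len(rows)


class TestParseCopyMatrix:
    def test_minimal_matrix_classified(self):
        frame = pd.DataFrame(
            {"Hugo_Symbol": ["A", "B"], "S1": ["-2", "0"], "S2": ["2", "1"]}
        )
        per_sample = parse_copy_matrix(frame)
        assert len(per_sample["S1"]) == len(per_sample["S2"]) == 2
        assert per_sample["S1"][0] == CopyVariant("A", -2.0, "deep_deletion")
        assert per_sample["S2"][0] == CopyVariant("A", 2.0, "amplification")
        assert per_sample["S2"][1].category == "neutral"

    def test_non_numeric_cell_rejected(self):
        frame = pd.DataFrame({"Hugo_Symbol": ["A"], "S1": ["oops"]})
        with pytest.raises(FormatError, match="non-numeric"):
            parse_copy_matrix(frame)


class TestParseExpressionMatrix:
    def test_rank_percentiles_and_directions(self):
        samples = {f"S{i}": [0.0] for i in range(39)}
        samples["S39"] = [4.0]
        frame = pd.DataFrame({"Hugo_Symbol": ["G"], **samples})
        per_sample = parse_expression_matrix(frame)
        top = per_sample["S39"][0]
        assert top.direction == "increased" and top.percentile == 100.0
        assert per_sample["S0"][0].direction == "none"

    def test_supplied_percentiles_override(self):
        frame = pd.DataFrame({"Hugo_Symbol": ["G"], "S1": [4.0]})
        pct = pd.DataFrame({"Hugo_Symbol": ["G"], "S1": [50.0]})
        per_sample = parse_expression_matrix(frame, percentiles=pct)
        assert per_sample["S1"][0].direction == "none"


class TestParseFusions:
    def test_pair_list(self):
        frame = pd.DataFrame(
            {
                "Hugo_Symbol": ["ATP1B1", ""],
                "Fusion_Partner": ["NRG1", "X"],
                "Tumor_Sample_Barcode": ["S1", "S1"],
            }
        )
        per_sample, dropped = parse_fusions(frame)
        assert per_sample == {"S1": [Fusion("ATP1B1", "NRG1")]}
        assert dropped == 1


class TestInvariantErrors:
    def test_small_mutation_requires_gene(self):
        with pytest.raises(FormatError):
            SmallMutation("", "p.G12D", "Missense_Mutation")

    def test_fusion_requires_both_genes(self):
        with pytest.raises(FormatError):
            Fusion("A", "")

    def test_expression_direction_checked(self):
        with pytest.raises(FormatError):
            ExpressionVariant("G", 0.0, 50.0, "sideways")
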