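{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "SampleReport",
  "type": "object",
  "required": [
    "sample_id",
    "diagnosis",
    "variant_counts",
    "matches",
    "unique_conclusions",
    "therapeutic_conclusions",
    "variant_type_group"
  ],
  "properties": {
    "sample_id": {"type": "string"},
    "diagnosis": {
      "type": "object",
      "required": ["oncotree_code", "cancer_type_detailed", "cancer_type"],
      "properties": {
        "oncotree_code": {"type": "string"},
        "cancer_type_detailed": {"type": "string"},
        "cancer_type": {"type": "string"}
      }
    },
    "variant_counts": {
      "type": "object",
      "additionalProperties": {"type": "integer"}
    },
    "matches": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "statement_id",
          "source_kb",
          "relevance",
          "subject",
          "relevance_category",
          "path_kind",
          "via_statement",
          "non_specific",
          "variant_types",
          "variants",
          "filter_flags"
        ],
        "properties": {
          "statement_id": {"type": "string"},
          "source_kb": {"type": "string"},
          "relevance": {"type": "string"},
          "subject": {"type": "string"},
          "relevance_category": {
            "type": "string",
            "enum": ["therapeutic", "diagnostic", "prognostic", "biological"]
          },
          "path_kind": {"type": "string", "enum": ["direct", "second_pass"]},
          "via_statement": {"type": ["string", "null"]},
          "non_specific": {"type": "boolean"},
          "variant_types": {
            "type": "array",
            "items": {"type": "string", "enum": ["mut", "cnv", "exp", "fus"]}
          },
          "variants": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["type"],
              "properties": {
                "type": {"type": "string", "enum": ["mut", "cnv", "exp", "fus"]},
                "gene": {"type": "string"},
                "protein_change": {"type": ["string", "null"]},
                "classification": {"type": "string"},
                "raw_value": {"type": "number"},
                "category": {"type": "string"},
                "z_score": {"type": "number"},
                "percentile": {"type": "number"},
                "direction": {"type": "string"},
                "gene5": {"type": "string"},
                "gene3": {"type": "string"}
              }
            }
          },
          "filter_flags": {
            "type": "object",
            "additionalProperties": {"type": "boolean"}
          }
        }
      }
    },
    "unique_conclusions": {"type": "integer"},
    "therapeutic_conclusions": {"type": "integer"},
    "variant_type_group": {
      "type": "array",
      "items": {"type": "string", "enum": ["mut", "cnv", "exp", "fus"]}
    }
  }
}
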