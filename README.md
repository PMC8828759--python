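# oncomatch

Graph knowledge base matching and reporting for somatic variant
interpretation. `oncomatch` stores ontology terms, inter-ontology links and
evidence statements in an in-memory graph, matches per-sample variants
(small mutations, copy calls, expression outliers, fusions) to those
statements directly and by single-hop ("second-pass") inference, applies
five therapeutic-applicability filters, and collates the results into
structured per-sample reports. It also quantifies cross-source conclusion
concordance before and after ontology normalization, and measures coverage
of clinical-trial-style terminology by ontology term sets.

All inputs are plain text. A seeded fixture generator produces complete,
self-consistent input bundles together with a manifest of planted truths, so
the whole pipeline can be exercised and verified offline.

## Running the tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance battery: brute-force oracle
equivalence for the matching engine, exhaustive filter-combination checks,
the evidence-tier table, threshold boundary grids, union-find equivalence for
ontology normalization, coverage properties, end-to-end parameter recovery
on a 100-sample synthetic cohort, and serialization round-trips. The
independent oracle implementations live in `tests/oracles.py`.

## Command-line interface

```bash
# generate a seeded synthetic input bundle (with truth manifest)
oncomatch simulate --seed 1 --out-dir bundle/ --samples 20

# load + validate a knowledge graph
oncomatch build-kb --terms bundle/terms.tsv --edges bundle/edges.tsv \
    --kb bundle/statements.jsonl

# match a cohort, optionally filtered
oncomatch match --terms bundle/terms.tsv --edges bundle/edges.tsv \
    --kb bundle/statements.jsonl --samples bundle/samples.tsv \
    --maf bundle/maf.tsv --cna bundle/cna.tsv \
    --expression bundle/expression.tsv --fusions bundle/fusions.tsv \
    --filters AMP_Tier_I,Diagnosis_Match --out matches.jsonl

# one JSON report per sample plus the cohort variant-type breakdown
oncomatch report --terms bundle/terms.tsv --edges bundle/edges.tsv \
    --kb bundle/statements.jsonl --samples bundle/samples.tsv \
    --maf bundle/maf.tsv --cna bundle/cna.tsv \
    --expression bundle/expression.tsv --fusions bundle/fusions.tsv \
    --out-dir reports/

# cross-source conclusion concordance (raw vs normalized)
oncomatch concordance --terms bundle/terms.tsv --edges bundle/edges.tsv \
    --kb bundle/statements.jsonl

# terminology coverage against registry-style records
oncomatch coverage --terms bundle/terms.tsv --edges bundle/edges.tsv \
    --registry bundle/registry.jsonl \
    --resources drugsa:therapy,drugsb:therapy,ncit:disease,oncotree:disease

# ontology reachability closure of a named term
oncomatch expand --terms bundle/terms.tsv --edges bundle/edges.tsv \
    --name "dx0" --edge-types alias_of,cross_reference,subclass_of
```

Thresholds, the synonymous-classification set, filter selection and the
evidence-tier map can be set in a flat `key = value` configuration file
passed with `--config` (see `oncomatch/config.py` for the key list).

## File dialects

* **Terms** (TSV): `source, sourceId, name, sourceIdVersion, termClass, isAlias`.
* **Edges** (TSV): endpoint key triples plus `edgeType` (one of
  `cross_reference, subclass_of, alias_of, element_of, generalizes`) and
  `assertedBy`.
* **Statements** (JSON Lines): `statementId, conditions, subject, relevance,
  evidence [{citationId, sourceLevel}], sourceKb, relevanceCategory`.
* **Small mutations** (TSV): `Hugo_Symbol, HGVSp_Short,
  Variant_Classification, Tumor_Sample_Barcode`; rows without a gene symbol
  are dropped.
* **Copy / expression matrices** (TSV): `Hugo_Symbol` plus one column per
  sample; copy calls classified at <= -2 / >= +2, expression outliers at
  z <= -2 / >= +2 combined (AND) with rank percentiles <= 2.5 / >= 97.5.
* **Fusions** (TSV): `Hugo_Symbol, Fusion_Partner, Tumor_Sample_Barcode`.
* **Registry records** (JSON Lines): `trialId, conditions,
  interventions [{name, type}]`; intervention types `Drug, Radiation,
  Combination Product, Dietary Supplement` count as therapy terms.
* **Sample metadata** (TSV): `sampleId, oncotreeCode, cancerTypeDetailed,
  cancerType`.

Variant conditions inside statements are `variant_class` terms whose names
follow a small grammar (`GENE:p.X`, `GENE mutation`, `GENE deep deletion`,
`GENE amplification`, `GENE increased|reduced expression`,
`GENE5::GENE3 fusion`, `GENE fusion`, and `REL mutations in GENE` for
functional characterizations reachable only via second-pass inference); see
`oncomatch/matching.py`.

Loaders for real external knowledge-base exports are out of scope; the
fixture generator stands in for them.
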