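# clinannotate

Dictionary-based annotation of clinical/biomedical free text, as a
standalone engine:

* **Concept recognition** — finds every occurrence of a terminology's
  preferred labels and synonyms at word boundaries (case- and
  punctuation-insensitive, whole-token, nested/overlapping matches
  kept), with optional is_a hierarchy expansion.
* **Scoring** — three per-document algorithms (`old` match-type weight
  sums, `cvalue`, `cvalueh`) built on a C-Value termhood measure that
  favours longer multi-word terms; filtering by absolute score or by
  nearest-rank percentile of the score distribution.
* **Clinical context** — rule-based negation / experiencer / temporality
  detection: trigger phrases with forward/backward scopes inside
  sentences, closed by colons or termination terms, with pseudo-phrase
  suppression. A ~140-entry English lexicon ships as a data file.
* **Semantic groups** — map fine-grained semantic-type codes to coarse
  groups (table-driven, NLM SemGroups layout) and filter annotations by
  group or type.
* **Serialization** — BRAT standoff (plus a reader), RDF N-Triples,
  JSON (1-based inclusive `from`/`to` offsets), and TSV.
* **Fixtures & evaluation** — reproducible synthetic terminologies and
  note corpora with planted gold annotations, and micro P/R/F1/accuracy
  scoring of predictions against them.

Internal offsets are 0-based code points, end-exclusive (BRAT
convention), everywhere.

## CLI

```sh
clinannotate --dict dict.tsv --input notes/ \
    --semantic-groups DISO --score cvalue --confidence-threshold 90 \
    --negation --experiencer --temporality \
    --format brat --output-dir out/
```

`--dict` takes a TSV with columns
`id  pref_label  synonyms  semantic_types  parents  source`
(multi-valued cells pipe-separated); `--skos` accepts a minimal SKOS
Turtle file (`skos:prefLabel` / `skos:altLabel` / `skos:broader`).
Other options: `--expand-hierarchy N`, `--semantic-types T047,T121`,
`--score-threshold X` (absolute), `--longest-only`,
`--format {json,brat,rdf,tsv}`, `--triggers FILE` (custom context
lexicon), `--context-window N`, `--config config.yaml`.
Run `clinannotate --help` for the full list.

## Library

```python
from clinannotate import (
    load_terminology, build_index, annotate_direct, apply_context,
    default_lexicon, score_annotations, ScoreConfig, filter_by_score,
)

term = load_terminology("dict.tsv", "tsv")
anns = annotate_direct(text, build_index(term))
anns = apply_context(text, anns, default_lexicon())
anns = score_annotations(anns, ScoreConfig(algorithm="cvalue"))
anns = filter_by_score(anns, "percentile", 90)
```

Synthetic corpora and evaluation:

```python
from clinannotate import CorpusParams, generate_corpus, run_pipeline, PipelineConfig, evaluate

term, corpus = generate_corpus(CorpusParams(n_concepts=5, n_notes=20, p_negation=0.5), seed=1)
pred = run_pipeline(PipelineConfig(negation=True), corpus.documents, terminology=term)
print(evaluate(pred, corpus, "spans").as_percent())
print(evaluate(pred, corpus, "negation").accuracy)
```

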