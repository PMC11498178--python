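# phenonorm

Extraction and normalization of abnormal key findings from short clinical
observation texts — dysmorphology physical-examination entries such as
`EYES: partial synophrys, long lashes, horizontal slant` — to
[Human Phenotype Ontology](https://hpo.jax.org/) (HPO) concepts, using a
large language model behind a pluggable, fully mockable backend.

It is written for clinical-NLP practitioners who want the *machinery* of an
LLM phenotype-normalization pipeline — prompt construction, span recovery,
dictionary normalization, evaluation — as a tested, offline-runnable
library, with the live model call isolated behind a one-method contract.

## The method

Generative models hallucinate both character offsets and ontology
identifiers, so the pipeline asks for neither. Each request instructs the
model to return a two-column table per finding:

```
| HPO Preferred Term | Marked Observation |
| long face | FACE: [elongated face]; flattened midface |
| midface retrusion | FACE: elongated face; [flattened midface] |
```

* **Marked text instead of offsets.** The model echoes the observation
  with the entity's span(s) wrapped in square brackets; 0-based,
  end-exclusive offsets are recovered by locating the brackets.
  Discontinuous entities (`MOUTH: [normal] lips, [tongue], …`) get one
  bracket pair per segment. Input text is pre-processed (`[`→`(`, `]`→`)`,
  length-stable) so brackets are unambiguous. If the echoed text differs
  from the original — models silently fix typos, or append stray
  characters — the prediction is **discarded**, not repaired.
* **Preferred terms instead of IDs.** The model names the concept; the
  concept ID comes from two-step dictionary matching. A dictionary maps
  normalized keys (case-folded, edge-punctuation-stripped, Porter-stemmed)
  to HPO IDs, built from ontology preferred terms, synonyms, and annotated
  training surfaces, minus a user-supplied exclusion list. Step 1 looks up
  the *observed* term (the bracketed surface form); on a miss, step 2 looks
  up the model's preferred term. An observed-only mode disables step 2,
  trading recall for precision.
* **Examples over instructions.** Behavior is taught by examples, either
  as an exported fine-tuning dataset (one system/user/assistant record per
  observation, chat JSONL) or by few-shot selection per request: the 15
  most similar annotated observations (cosine of mean token vectors), 5
  curated "tricky" examples for the query's organ system (disjoint spans,
  modifier exclusion, organ-header annotation), and the 5 most similar
  empty observations — 25 in total, shuffled.
* **Scoring.** Micro-averaged P/R/F1 under three settings: concept ID only
  (*normalization-only*), ID plus any character overlap (*overlapping*),
  ID plus identical spans (*strict*), with one-to-one matching per
  observation.

A synthetic-corpus generator emulates the structure of real data (12%
empty observations, ~14% discontinuous spans, ~1.49 findings per non-empty
observation, 20 organ systems, modifier injection, out-of-ontology
paraphrases), so every stage is testable offline against a deterministic
replay backend.

## Worked example

```python
from phenonorm import recover_spans, build_dictionary, normalize_entity, OntologyTerm
from phenonorm.response_parser import parse_entity_table

text = "FACE: elongated face; flattened midface"
response = ("| HPO Preferred Term | Marked Observation |\n"
            "| long face | FACE: [elongated face]; flattened midface |")
pred = parse_entity_table(response, text)[0]
print(pred.spans.segments, pred.observed_term)
# ((6, 20),) elongated face

dictionary = build_dictionary([OntologyTerm("HP:0000276", "long face")])
result = normalize_entity(pred, dictionary)
print(result.hpo_id, result.step.value)
# HP:0000276 preferred
```

The spans `(6, 20)` select `"elongated face"` in the original text; the
surface form is not in the dictionary, so normalization falls through to
the model's preferred term `"long face"`, which resolves to `HP:0000276`.
The `examples/` directory has one runnable script per capability (span
codec, curation, few-shot selection, normalization, end-to-end replay),
each printing and explaining its output. A `phenonorm` CLI exposes every
stage (`synth`, `curate`, `build-dict`, `export-finetune`,
`select-fewshot`, `run`, `evaluate`).

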