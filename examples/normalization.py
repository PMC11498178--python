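"""Two-step dictionary normalization: observed term first, preferred second.

The dictionary maps stemmed, case-folded keys to HPO IDs, built from the
ontology's preferred terms and synonyms (plus training surfaces when
available).  A prediction is first looked up by the surface form that
actually appears in the text; only on a miss is the model-proposed
preferred term tried.
"""

from phenonorm import OntologyTerm, SpanSet, build_dictionary, normalize_entity
from phenonorm.normalizer import NormalizationMode
from phenonorm.response_parser import EntityPrediction

terms = [
    OntologyTerm("HP:0000276", "long face", ("elongated face",)),
    OntologyTerm("HP:0000218", "high palate"),
]
dictionary = build_dictionary(terms)

# "Elongated Face" is a registered synonym: resolved at the observed step,
# despite the casing difference (keys are case-folded and stemmed).
pred = EntityPrediction("long face", "Elongated Face", SpanSet(((6, 20),)))
result = normalize_entity(pred, dictionary)
print(f"observed {pred.observed_term!r} -> {result.hpo_id} "
      f"(step: {result.step.value})")

# "lengthened face" is not in the ontology; the model's preferred term is.
pred = EntityPrediction("long face", "lengthened face", SpanSet(((6, 21),)))
result = normalize_entity(pred, dictionary)
print(f"observed {pred.observed_term!r} -> {result.hpo_id} "
      f"(step: {result.step.value})")

# The observed-only mode disables the fallback: higher precision, lower
# recall, since the model's preferred-term guesses are never trusted.
result = normalize_entity(pred, dictionary, NormalizationMode.OBSERVED_ONLY)
print(f"observed-only mode      -> {result.hpo_id} (step: {result.step.value})")
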