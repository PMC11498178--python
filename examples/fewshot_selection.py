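"""Three-step few-shot selection: 15 similar positives + 5 tricky + 5
negatives, shuffled.

Every inference request gets its own 25 worked examples: the most similar
annotated observations teach the output format on related content, the
curated "tricky" list for the query's organ system teaches boundary rules
(disjoint spans, modifier exclusion, header annotation), and the most
similar empty observations teach the no-findings response.
"""

from collections import Counter

from phenonorm import ExamplePool, SelectionConfig, select_examples
from phenonorm.synthetic import SyntheticConfig, generate_corpus

corpus = generate_corpus(SyntheticConfig(seed=42, n_observations=200))
lookup = {t.hpo_id: t.preferred_term for t in corpus.ontology}
pool = ExamplePool.from_corpus(corpus.observations, corpus.annotations, lookup)
print(f"pool: {len(pool.positives)} annotated, {len(pool.negatives)} empty")

query = pool.positives[0].user_content
examples = select_examples(query, pool, corpus.registry,
                           SelectionConfig(shuffle_seed=0))
counts = Counter(e.category.value for e in examples)
print(f"query: {query}")
print(f"selected {len(examples)} examples: {dict(counts)}")
# 25 total = 15 similar_positive + 5 tricky + 5 negative whenever the pool
# suffices; shuffling only permutes, never changes the composition.

print("\nfirst three after shuffling:")
for example in examples[:3]:
    print(f"  [{example.category.value}] {example.user_content}")
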