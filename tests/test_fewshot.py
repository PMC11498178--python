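import math
from collections import Counter

import numpy as np
import pytest

from phenonorm.fewshot import (ExampleCategory, ExamplePool, FewShotExample,
                               HashEmbedder, SelectionConfig, TrickyRegistry,
                               select_examples, text_similarity)
from phenonorm.response_parser import parse_entity_table


class FixedEmbedder:
    """Hand-specified token vectors for oracle-checked cosine values."""

    def __init__(self, table):
        self.table = table

    def embed(self, token):
        return np.asarray(self.table[token], dtype=float)


class TestTextSimilarity:
    def test_identical_texts(self):
        embedder = HashEmbedder()
        assert text_similarity("long face", "long face", embedder) == \
            pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_single_tokens(self):
        embedder = FixedEmbedder({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        assert text_similarity("a", "b", embedder) == pytest.approx(0.0)

    def test_hand_computed_cosine(self):
        # mean("a b") = (0.5, 0.5); mean("c d") = (1, 0.5)
        embedder = FixedEmbedder({"a": [1.0, 0.0], "b": [0.0, 1.0],
                                  "c": [2.0, 0.0], "d": [0.0, 1.0]})
        expected = (0.5 * 1 + 0.5 * 0.5) / (
            math.sqrt(0.5) * math.sqrt(1.25))
        assert text_similarity("a b", "c d", embedder) == \
            pytest.approx(expected, abs=1e-12)

    def test_no_embeddable_tokens(self):
        embedder = HashEmbedder()
        assert text_similarity("", "long face", embedder) == 0.0
        assert text_similarity("...", "long face", embedder) == 0.0

    def test_range(self, small_corpus):
        embedder = HashEmbedder()
        texts = [o.text for o in small_corpus.observations[:30]]
        for a in texts[:5]:
            for b in texts:
                assert -1.0 - 1e-9 <= text_similarity(a, b, embedder) <= 1.0 + 1e-9


@pytest.fixture(scope="module")
def pool_and_registry():
    from phenonorm.synthetic import SyntheticConfig, generate_corpus
    corpus = generate_corpus(SyntheticConfig(seed=5, n_observations=150))
    lookup = {t.hpo_id: t.preferred_term for t in corpus.ontology}
    pool = ExamplePool.from_corpus(corpus.observations, corpus.annotations,
                                   lookup)
    return pool, corpus.registry, corpus


class TestSelection:
    def test_default_budget_and_composition(self, pool_and_registry):
        pool, registry, corpus = pool_and_registry
        query = pool.positives[0].user_content
        examples = select_examples(query, pool, registry)
        assert len(examples) == 25
        counts = Counter(e.category for e in examples)
        assert counts[ExampleCategory.SIMILAR_POSITIVE] == 15
        assert counts[ExampleCategory.TRICKY] == 5
        assert counts[ExampleCategory.NEGATIVE] == 5

    def test_positive_examples_have_entities_negatives_none(
            self, pool_and_registry):
        pool, registry, _ = pool_and_registry
        query = pool.positives[0].user_content
        for example in select_examples(query, pool, registry):
            n_entities = len(parse_entity_table(example.assistant_content,
                                                example.user_content))
            if example.category is ExampleCategory.SIMILAR_POSITIVE:
                assert n_entities >= 1
            elif example.category is ExampleCategory.NEGATIVE:
                assert n_entities == 0

    def test_shortfall_takes_all_available(self, pool_and_registry):
        pool, registry, _ = pool_and_registry
        short_pool = ExamplePool(pool.positives[:3], pool.negatives[:1])
        examples = select_examples("EYES: anything", short_pool, registry)
        assert len(examples) == 3 + 5 + 1
        counts = Counter(e.category for e in examples)
        assert counts[ExampleCategory.SIMILAR_POSITIVE] == 3
        assert counts[ExampleCategory.NEGATIVE] == 1

    def test_fixed_seed_reproducible(self, pool_and_registry):
        pool, registry, _ = pool_and_registry
        query = pool.positives[3].user_content
        cfg = SelectionConfig(shuffle_seed=99)
        first = select_examples(query, pool, registry, cfg)
        second = select_examples(query, pool, registry, cfg)
        assert first == second

    def test_shuffle_is_permutation(self, pool_and_registry):
        pool, registry, _ = pool_and_registry
        query = pool.positives[0].user_content
        for seed in (0, 1, 2):
            cfg = SelectionConfig(shuffle_seed=seed)
            examples = select_examples(query, pool, registry, cfg)
            counts = Counter(e.category for e in examples)
            assert counts == {ExampleCategory.SIMILAR_POSITIVE: 15,
                              ExampleCategory.TRICKY: 5,
                              ExampleCategory.NEGATIVE: 5}

    def test_selected_positives_dominate_unselected(self, pool_and_registry):
        pool, registry, _ = pool_and_registry
        embedder = HashEmbedder()
        query = pool.positives[7].user_content
        examples = select_examples(query, pool, registry, embedder=embedder)
        chosen_ids = {e.source_id for e in examples
                      if e.category is ExampleCategory.SIMILAR_POSITIVE}
        chosen_scores = [text_similarity(query, e.user_content, embedder)
                         for e in pool.positives if e.source_id in chosen_ids]
        unchosen_scores = [text_similarity(query, e.user_content, embedder)
                           for e in pool.positives
                           if e.source_id not in chosen_ids]
        assert min(chosen_scores) >= max(unchosen_scores) - 1e-12

    def test_tricky_fallback_for_unknown_header(self, pool_and_registry):
        pool, registry, _ = pool_and_registry
        examples = select_examples("UNREGISTERED: some text", pool, registry)
        tricky = [e for e in examples if e.category is ExampleCategory.TRICKY]
        assert len(tricky) == 5
        assert tricky[0].source_id.startswith("tricky:")

    def test_empty_pool_is_error(self, pool_and_registry):
        _, registry, _ = pool_and_registry
        with pytest.raises(ValueError, match="empty"):
            select_examples("EYES: x", ExamplePool([], []), registry)


class TestTrickyRegistry:
    def test_exactly_five_enforced(self):
        registry = TrickyRegistry()
        example = FewShotExample("u", "a", ExampleCategory.TRICKY, "s")
        with pytest.raises(ValueError, match="exactly 5"):
            registry.register("EYES", [example] * 4)

    def test_json_round_trip(self, tmp_path, pool_and_registry):
        _, registry, _ = pool_and_registry
        path = tmp_path / "registry.json"
        registry.to_json(path)
        loaded = TrickyRegistry.from_json(path)
        assert loaded.by_header == registry.by_header
        assert loaded.default == registry.default

    def test_registry_demonstrates_task_behaviors(self, pool_and_registry):
        """Each header's list covers disjoint spans, modifier exclusion and
        organ-header annotation."""
        _, registry, _ = pool_and_registry
        for header, examples in registry.by_header.items():
            tags = {e.source_id.rsplit(":", 1)[-1] for e in examples}
            assert {"disjoint", "modifier", "header-disjoint", "header-full",
                    "combined"} <= tags
            for example in examples:
                predictions = parse_entity_table(example.assistant_content,
                                                 example.user_content)
                assert predictions and not any(p.discarded
                                               for p in predictions)
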