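import random

import pytest

from phenonorm.corpus_io import (FindingAnnotation, Observation, Polarity,
                                 SpanSet)
from phenonorm.synthetic import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A 120-observation synthetic corpus shared across tests."""
    return generate_corpus(SyntheticConfig(seed=11, n_observations=120))


@pytest.fixture(scope="session")
def preferred_lookup(small_corpus):
    return {t.hpo_id: t.preferred_term for t in small_corpus.ontology}


@pytest.fixture()
def exam_observations():
    """Hand-built observations mirroring the worked corpus examples."""
    return [
        Observation("obs-eyes",
                    "EYES: partial synophrys, long lashes, horizontal slant"),
        Observation("obs-mouth", "MOUTH: normal lips, tongue, high palate"),
        Observation("obs-neuro", "NEUROLOGIC: very active"),
    ]


@pytest.fixture()
def exam_annotations():
    return [
        FindingAnnotation("obs-eyes", "HP:0000664", SpanSet(((14, 23),)),
                          Polarity.ABNORMAL),
        FindingAnnotation("obs-eyes", "HP:0000527", SpanSet(((25, 36),)),
                          Polarity.ABNORMAL),
        FindingAnnotation("obs-mouth", "HP:0000218", SpanSet(((28, 39),)),
                          Polarity.ABNORMAL),
        FindingAnnotation("obs-mouth", "HP:0000159", SpanSet(((7, 18),)),
                          Polarity.NORMAL),
        FindingAnnotation("obs-mouth", "HP:0000157", SpanSet(((7, 13), (20, 26))),
                          Polarity.NORMAL),
    ]


def random_spanset(rng: random.Random, text_len: int) -> SpanSet:
    """Random valid span set for a text of the given length."""
    segments = []
    pos = 0
    for _ in range(rng.randint(0, 4)):
        if pos >= text_len - 1:
            break
        start = rng.randint(pos, text_len - 1)
        end = rng.randint(start + 1, text_len)
        segments.append((start, end))
        pos = end
    return SpanSet(tuple(segments))
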