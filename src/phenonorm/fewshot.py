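"""Custom few-shot example selection.

Each inference request carries 25 worked examples chosen for that specific
query in three steps: (1) the 15 training observations most semantically
similar to the query that contain at least one finding; (2) a hand-curated
list of 5 "tricky" examples for the query's organ system, demonstrating
task behaviors models tend to violate — disjoint spans, modifier exclusion,
organ-header annotation; (3) the 5 negative (no-finding) training
observations most similar to the query, teaching the empty-output format.
The combined list is then shuffled so category blocks do not form a
positional pattern.

Similarity is the cosine of mean token vectors.  The token embedder is an
injected provider; the default derives a deterministic vector per token
from a hash of the token, which preserves the algorithm's structure (exact
matches score 1, disjoint vocabularies score near 0) while remaining fully
offline.  An adapter for real pretrained vectors plugs in through the same
protocol.
"""

from __future__ import annotations

import hashlib
import json
import logging
import random
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np

from .corpus_io import FindingAnnotation, Observation
from .prompting import annotations_to_rows, preprocess_text, render_entity_table

logger = logging.getLogger(__name__)


class ExampleCategory(str, Enum):
    SIMILAR_POSITIVE = "similar_positive"
    TRICKY = "tricky"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class FewShotExample:
    user_content: str
    assistant_content: str
    category: ExampleCategory
    source_id: str


class TokenEmbedder(Protocol):
    """Provider of one fixed-dimension vector per token."""

    def embed(self, token: str) -> np.ndarray: ...


class HashEmbedder:
    """Deterministic per-token random vectors seeded from a token hash.

    Identical tokens always get identical vectors, so texts sharing words
    score high; unrelated vocabularies give near-orthogonal means.  Purely
    offline and reproducible across processes.
    """

    def __init__(self, dim: int = 64, salt: str = "phenonorm") -> None:
        self.dim = dim
        self.salt = salt
        self._cache: dict[str, np.ndarray] = {}

    def embed(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(f"{self.salt}:{token}".encode(),
                                     digest_size=8).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            vec = rng.standard_normal(self.dim)
            self._cache[token] = vec
        return vec


def _tokenize(text: str) -> list[str]:
    return [tok for tok in
            "".join(c if c.isalnum() else " " for c in text.casefold()).split()
            if tok]


def text_similarity(a: str, b: str, embedder: TokenEmbedder) -> float:
    """Cosine similarity of the mean token vectors of two texts; 0.0 when
    either text has no embeddable tokens."""
    tokens_a, tokens_b = _tokenize(a), _tokenize(b)
    if not tokens_a or not tokens_b:
        return 0.0
    mean_a = np.mean([embedder.embed(t) for t in tokens_a], axis=0)
    mean_b = np.mean([embedder.embed(t) for t in tokens_b], axis=0)
    norm = float(np.linalg.norm(mean_a) * np.linalg.norm(mean_b))
    if norm == 0.0:
        return 0.0
    return float(np.dot(mean_a, mean_b) / norm)


@dataclass(frozen=True)
class SelectionConfig:
    """Budget split and shuffle seed for one selection (default 15+5+5=25)."""

    k_similar: int = 15
    k_tricky: int = 5
    k_negative: int = 5
    shuffle_seed: int = 0

    @property
    def budget(self) -> int:
        return self.k_similar + self.k_tricky + self.k_negative


@dataclass
class TrickyRegistry:
    """Per-organ-header lists of exactly 5 curated tricky examples, plus an
    optional default list for unregistered headers."""

    by_header: dict[str, list[FewShotExample]] = field(default_factory=dict)
    default: list[FewShotExample] = field(default_factory=list)

    def register(self, header: str, examples: Sequence[FewShotExample]) -> None:
        if len(examples) != 5:
            raise ValueError(f"tricky list for {header!r} must have exactly 5 "
                             f"examples, got {len(examples)}")
        self.by_header[header.upper()] = list(examples)

    def for_header(self, header: str) -> list[FewShotExample]:
        examples = self.by_header.get(header.upper())
        if examples is None:
            if not self.default:
                logger.warning("no tricky examples for header %r and no "
                               "default list", header)
                return []
            return list(self.default)
        return examples

    def to_json(self, path: str | Path) -> None:
        payload = {
            "by_header": {h: [e.__dict__ | {"category": e.category.value}
                              for e in ex] for h, ex in self.by_header.items()},
            "default": [e.__dict__ | {"category": e.category.value}
                        for e in self.default],
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "TrickyRegistry":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))

        def load(items):
            return [FewShotExample(d["user_content"], d["assistant_content"],
                                   ExampleCategory(d["category"]),
                                   d["source_id"]) for d in items]

        registry = cls()
        for header, items in payload.get("by_header", {}).items():
            registry.register(header, load(items))
        registry.default = load(payload.get("default", []))
        return registry


@dataclass
class ExamplePool:
    """Training observations rendered as ready-to-use few-shot examples,
    split into positives (>= 1 finding) and negatives (no findings).  Pool
    order is preserved for stable tie-breaking."""

    positives: list[FewShotExample]
    negatives: list[FewShotExample]

    @classmethod
    def from_corpus(
        cls,
        observations: Sequence[Observation],
        annotations: Sequence[FindingAnnotation],
        preferred_lookup: Mapping[str, str],
    ) -> "ExamplePool":
        by_obs: dict[str, list[FindingAnnotation]] = {o.id: [] for o in observations}
        for ann in annotations:
            by_obs[ann.observation_id].append(ann)
        positives, negatives = [], []
        for obs in observations:
            anns = by_obs[obs.id]
            category = (ExampleCategory.SIMILAR_POSITIVE if anns
                        else ExampleCategory.NEGATIVE)
            table = render_entity_table(
                annotations_to_rows(obs, anns, preferred_lookup))
            example = FewShotExample(preprocess_text(obs.text), table,
                                     category, obs.id)
            (positives if anns else negatives).append(example)
        return cls(positives, negatives)


def _top_k(query: str, candidates: Sequence[FewShotExample], k: int,
           embedder: TokenEmbedder) -> list[FewShotExample]:
    scored = [(text_similarity(query, ex.user_content, embedder), -i, ex)
              for i, ex in enumerate(candidates)]
    scored.sort(key=lambda t: (t[0], t[1]), reverse=True)  # ties: pool order
    return [ex for _, _, ex in scored[:k]]


def select_examples(
    query_text: str,
    pool: ExamplePool,
    registry: TrickyRegistry,
    cfg: SelectionConfig = SelectionConfig(),
    embedder: TokenEmbedder | None = None,
) -> list[FewShotExample]:
    """Run the three-step selection for one pre-processed query text.

    Returns at most ``cfg.budget`` examples, shuffled with
    ``cfg.shuffle_seed``; when a category has fewer members than requested,
    all available are taken and the shortfall is logged.  An empty pool is
    an error.
    """
    if not pool.positives and not pool.negatives:
        raise ValueError("example pool is empty")
    embedder = embedder or HashEmbedder()

    header, sep, _ = query_text.partition(":")
    organ_header = header.upper() if sep else ""

    similar = _top_k(query_text, pool.positives, cfg.k_similar, embedder)
    tricky = registry.for_header(organ_header)[:cfg.k_tricky]
    negative = _top_k(query_text, pool.negatives, cfg.k_negative, embedder)

    for name, got, want in (("similar_positive", len(similar), cfg.k_similar),
                            ("tricky", len(tricky), cfg.k_tricky),
                            ("negative", len(negative), cfg.k_negative)):
        if got < want:
            logger.info("few-shot shortfall: %s has %d of %d requested",
                        name, got, want)

    selected = similar + tricky + negative
    random.Random(cfg.shuffle_seed).shuffle(selected)
    return selected
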