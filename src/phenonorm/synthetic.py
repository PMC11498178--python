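"""Synthetic dysmorphology-style corpora for offline development and testing.

Real observations are one-line organ-system entries — an upper-case header,
a colon, then comma- or semicolon-separated findings ("EYES: partial
synophrys, long lashes").  The generator emulates the structural features
the pipeline exercises, at the rates observed in the shared-task data:
roughly 12% of observations are empty (no findings), about 14% of gold
spans are discontinuous, findings per non-empty observation follow a
zero-truncated Poisson with mean ~1.49, and 20 organ systems appear.  On
top of that it injects the phenomena the method must survive: modifier
words ("mild", "slightly") excluded from gold boundaries, surface
paraphrases that are absent from the ontology (forcing the preferred-term
normalization path), and normal-polarity findings that curation must drop.

What it does not emulate: real clinical vocabulary breadth, typos, or
cross-observation patient structure.  Pipeline tests passing on synthetic
corpora demonstrate the machinery (codec, selection, normalization,
scoring), not clinical extraction quality.

Everything is driven by one integer seed; the same seed yields a
byte-identical corpus.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

from .corpus_io import (FindingAnnotation, Observation, OntologyTerm,
                        Polarity, SpanSet)
from .fewshot import ExampleCategory, FewShotExample, TrickyRegistry
from .prompting import EntityTableRow, mark_text, render_entity_table

#: Zero-truncated Poisson rate giving a mean of ~1.49 findings/observation.
CONCEPT_RATE = 0.859

DEFAULT_ORGAN_SYSTEMS = (
    "EYES", "EARS", "MOUTH", "NOSE", "FACE", "NECK", "HEAD", "NEUROLOGIC",
    "SKIN", "HANDS", "FEET", "CHEST", "ABDOMEN", "BACK", "GENITALIA",
    "CARDIOVASCULAR", "RESPIRATORY", "MUSCULOSKELETAL", "HAIR", "EXTREMITIES",
)

#: Adjective triples: (preferred wording, registered synonym wording,
#: unregistered paraphrase wording).  All three stem to distinct keys.
_ADJECTIVE_TRIPLES = (
    ("long", "elongated", "lengthened"),
    ("short", "shortened", "foreshortened"),
    ("broad", "widened", "broadened"),
    ("narrow", "slender", "constricted"),
    ("thin", "fine", "attenuated"),
    ("thick", "coarse", "bulky"),
    ("flat", "flattened", "planar"),
    ("deep", "sunken", "recessed"),
    ("bulbous", "rounded", "globular"),
    ("crumpled", "folded", "wrinkled"),
    ("upslanted", "upward-slanting", "oblique"),
    ("low-set", "inferiorly-placed", "depressed"),
    ("pointed", "tapered", "conical"),
    ("smooth", "effaced", "featureless"),
    ("sparse", "scant", "meager"),
    ("redundant", "excess", "surplus"),
)

_NOUNS = (
    "forehead", "palate", "philtrum", "nasal bridge", "helix", "lip",
    "chin", "jaw", "nuchal fold", "finger", "toe", "thumb", "palmar crease",
    "skull", "hairline", "eyebrow", "eyelid", "nostril", "tongue", "cheek",
)

#: Modifier words injected before findings and excluded from gold spans.
_MODIFIERS = ("mild", "mildly", "slightly", "very", "prominent")

#: Words splitting a disjoint finding ("[Low-set] left [ear]" pattern).
_SPLITTERS = ("left", "right", "appearing")

_FILLER_SENTENCES = (
    "normal exam", "unremarkable", "within normal limits", "very active",
    "no abnormalities noted", "well appearing", "normal for age",
)

#: In-corpus exemplar concepts kept as fixed fixtures in every mini-ontology.
FIXTURE_TERMS = (
    OntologyTerm("HP:0005989", "redundant neck skin", ("excess neck skin",)),
    OntologyTerm("HP:0000474", "thickened nuchal skin fold",
                 ("excess nuchal skin",)),
    OntologyTerm("HP:0000218", "high palate", ("elevated palate",)),
    OntologyTerm("HP:0000664", "synophrys", ("fused eyebrows",)),
)


def generate_mini_ontology(seed: int, n_terms: int = 60) -> list[OntologyTerm]:
    """Generate ``n_terms`` synthetic HPO-style concepts.

    Preferred terms are adjective+noun phrases; each concept carries 0-3
    synonyms built from registered adjective variants.  The fixture
    exemplars above are always included (within the requested count when it
    allows).  Same seed, same output.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = random.Random(seed)
    terms: list[OntologyTerm] = list(FIXTURE_TERMS[:n_terms])

    combos = [(a, n) for a in range(len(_ADJECTIVE_TRIPLES))
              for n in range(len(_NOUNS))]
    rng.shuffle(combos)
    next_id = 100
    for adj_idx, noun_idx in combos:
        if len(terms) >= n_terms:
            break
        preferred_adj, synonym_adj, _ = _ADJECTIVE_TRIPLES[adj_idx]
        noun = _NOUNS[noun_idx]
        preferred = f"{preferred_adj} {noun}"
        candidates = [f"{synonym_adj} {noun}",
                      f"{preferred_adj} {noun} appearance",
                      f"{synonym_adj} {noun} appearance"]
        synonyms = tuple(candidates[:rng.randint(0, 3)])
        terms.append(OntologyTerm(f"HP:{next_id:07d}", preferred, synonyms))
        next_id += 1
    if len(terms) < n_terms:
        raise ValueError(f"cannot generate {n_terms} unique terms "
                         f"({len(terms)} combinations available)")
    return terms


def paraphrase_surface(term: OntologyTerm) -> str:
    """An out-of-ontology paraphrase of a concept's preferred term.

    For adjective+noun terms whose adjective has a registered variant
    triple, the unregistered third wording is used; otherwise the preferred
    term is prefixed with "atypical".  Either way the result is not among
    the concept's ontology surfaces, so observed-term lookup misses and
    normalization must fall through to the preferred term.
    """
    first, _, rest = term.preferred_term.partition(" ")
    for preferred_adj, _, paraphrase_adj in _ADJECTIVE_TRIPLES:
        if first == preferred_adj and rest:
            return f"{paraphrase_adj} {rest}"
    return f"atypical {term.preferred_term}"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; defaults reproduce the corpus statistics the
    pipeline was designed around (see module docstring)."""

    seed: int = 0
    n_observations: int = 500
    empty_rate: float = 0.12
    disjoint_rate: float = 0.14
    concepts_per_observation_mean: float = 1.49
    organ_systems: tuple[str, ...] = DEFAULT_ORGAN_SYSTEMS
    modifier_rate: float = 0.15
    paraphrase_rate: float = 0.20
    normal_rate: float = 0.10

    def __post_init__(self) -> None:
        for name in ("empty_rate", "disjoint_rate", "modifier_rate",
                     "paraphrase_rate", "normal_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_observations < 1:
            raise ValueError("n_observations must be positive")


@dataclass
class CorpusStats:
    """Generation bookkeeping for tolerance and subset tests."""

    n_empty: int = 0
    n_disjoint_spans: int = 0
    n_annotations: int = 0
    n_normal: int = 0
    n_modifier: int = 0
    #: (observation_id, hpo_id) keys of paraphrased-surface findings.
    paraphrased: set = field(default_factory=set)

    @property
    def empty_fraction(self) -> float:
        return self.n_empty / max(1, self.n_empty + self._n_nonempty)

    _n_nonempty: int = 0


@dataclass
class SyntheticCorpus:
    observations: list[Observation]
    annotations: list[FindingAnnotation]
    registry: TrickyRegistry
    negatives: list[Observation]
    ontology: list[OntologyTerm]
    stats: CorpusStats


def _truncated_poisson(rng: random.Random, rate: float) -> int:
    """Zero-truncated Poisson draw (Knuth multiplication, rejecting 0)."""
    threshold = math.exp(-rate)
    while True:
        k, p = 0, 1.0
        while p > threshold:
            k += 1
            p *= rng.random()
        if k - 1 >= 1:
            return k - 1


def _build_finding(rng: random.Random, term: OntologyTerm, surface: str,
                   normal: bool, disjoint: bool, with_modifier: bool,
                   offset: int) -> tuple[str, SpanSet, int]:
    """Realize one finding as text starting at ``offset``; returns the text
    chunk, the gold span set (offsets into the full observation), and the
    modifier-prefix length."""
    prefix = ""
    if normal:
        # normal findings carry the "normal" wording inside the gold span
        surface = f"normal {surface}"
    elif with_modifier:
        prefix = rng.choice(_MODIFIERS) + " "

    words = surface.split()
    if disjoint and len(words) >= 2 and not normal:
        splitter = rng.choice(_SPLITTERS)
        head = " ".join(words[:-1])
        tail = words[-1]
        chunk = f"{prefix}{head} {splitter} {tail}"
        start = offset + len(prefix)
        seg1 = (start, start + len(head))
        tail_start = start + len(head) + 1 + len(splitter) + 1
        seg2 = (tail_start, tail_start + len(tail))
        return chunk, SpanSet((seg1, seg2)), len(prefix)
    chunk = f"{prefix}{surface}"
    start = offset + len(prefix)
    return chunk, SpanSet(((start, start + len(surface)),)), len(prefix)


def _tricky_examples_for(header: str, terms: Sequence[OntologyTerm],
                         rng: random.Random) -> list[FewShotExample]:
    """Five examples demonstrating the task behaviors models tend to break:
    disjoint spans, modifier exclusion, organ-header annotation, and their
    combination."""
    pool = [t for t in terms if " " in t.preferred_term] or list(terms)
    picks = [pool[rng.randrange(len(pool))] for _ in range(5)]
    examples = []

    def make(source_tag: str, text: str, spans: SpanSet,
             term: OntologyTerm) -> FewShotExample:
        table = render_entity_table(
            [EntityTableRow(term.preferred_term, mark_text(text, spans))])
        return FewShotExample(text, table, ExampleCategory.TRICKY,
                              f"tricky:{header}:{source_tag}")

    # disjoint span: "EARS: Low-set left ear" -> [Low-set] left [ear]
    term = picks[0]
    words = term.preferred_term.split()
    head, tail = " ".join(words[:-1]), words[-1]
    text = f"{header}: {head} left {tail}" if len(words) > 1 \
        else f"{header}: {head} appearing {head}"
    base = len(header) + 2
    if len(words) > 1:
        spans = SpanSet(((base, base + len(head)),
                         (base + len(head) + 6, base + len(head) + 6 + len(tail))))
    else:
        spans = SpanSet(((base, base + len(head)),))
    examples.append(make("disjoint", text, spans, term))

    # modifier exclusion: "EYES: Mildly low-set ear" -> Mildly [low-set ear]
    term = picks[1]
    text = f"{header}: mildly {term.preferred_term}"
    start = len(header) + 9
    spans = SpanSet(((start, start + len(term.preferred_term)),))
    examples.append(make("modifier", text, spans, term))

    # organ-header annotation, disjoint with the header: "[EAR]: [crumpled]"
    term = picks[2]
    adjective = term.preferred_term.split()[0]
    text = f"{header}: {adjective}"
    spans = SpanSet(((0, len(header)), (len(header) + 2,
                                        len(header) + 2 + len(adjective))))
    examples.append(make("header-disjoint", text, spans, term))

    # organ-header annotation, full term in body: "EAR: [crumpled ear]"
    term = picks[3]
    text = f"{header}: {term.preferred_term}"
    spans = SpanSet(((len(header) + 2,
                      len(header) + 2 + len(term.preferred_term)),))
    examples.append(make("header-full", text, spans, term))

    # all of the above: "[NOSE]: slightly [bulbous]"
    term = picks[4]
    adjective = term.preferred_term.split()[0]
    text = f"{header}: slightly {adjective}"
    start = len(header) + 11
    spans = SpanSet(((0, len(header)), (start, start + len(adjective))))
    examples.append(make("combined", text, spans, term))
    return examples


def generate_corpus(cfg: SyntheticConfig,
                    ontology: Sequence[OntologyTerm] | None = None,
                    ) -> SyntheticCorpus:
    """Generate a full synthetic corpus under ``cfg``.

    Returns observations, gold annotations, a tricky-example registry
    covering every configured organ system, the negative (empty)
    observations, the ontology used, and generation bookkeeping.  Same
    config, byte-identical output.
    """
    rng = random.Random(cfg.seed)
    if ontology is None:
        ontology = generate_mini_ontology(rng.randrange(2**31), n_terms=60)
    if not ontology:
        raise ValueError("ontology must be non-empty")

    observations: list[Observation] = []
    annotations: list[FindingAnnotation] = []
    negatives: list[Observation] = []
    stats = CorpusStats()

    for _ in range(cfg.n_observations):
        obs_id = f"{rng.getrandbits(60):015x}"
        header = cfg.organ_systems[rng.randrange(len(cfg.organ_systems))]
        if rng.random() < cfg.empty_rate:
            filler = rng.choice(_FILLER_SENTENCES)
            obs = Observation(obs_id, f"{header}: {filler}")
            observations.append(obs)
            negatives.append(obs)
            stats.n_empty += 1
            continue
        stats._n_nonempty += 1

        k = min(_truncated_poisson(rng, CONCEPT_RATE), len(ontology))
        terms = rng.sample(list(ontology), k)
        text = f"{header}: "
        obs_annotations = []
        for i, term in enumerate(terms):
            normal = rng.random() < cfg.normal_rate
            paraphrase = (not normal) and rng.random() < cfg.paraphrase_rate
            surface = paraphrase_surface(term) if paraphrase \
                else term.preferred_term
            disjoint = rng.random() < cfg.disjoint_rate
            with_modifier = rng.random() < cfg.modifier_rate

            if i > 0:
                text += rng.choice((", ", "; "))
            chunk, spans, _ = _build_finding(rng, term, surface, normal,
                                             disjoint, with_modifier,
                                             len(text))
            text += chunk
            polarity = Polarity.NORMAL if normal else Polarity.ABNORMAL
            obs_annotations.append(
                FindingAnnotation(obs_id, term.hpo_id, spans, polarity))
            if normal:
                stats.n_normal += 1
            if len(spans) > 1:
                stats.n_disjoint_spans += 1
            if with_modifier and not normal:
                stats.n_modifier += 1
            if paraphrase:
                stats.paraphrased.add((obs_id, term.hpo_id))
        obs = Observation(obs_id, text)
        observations.append(obs)
        for ann in obs_annotations:
            if not ann.spans.valid_for(obs.text) or \
                    ann.spans.extract(obs.text) == "":
                raise AssertionError("generator produced invalid spans")
            annotations.append(ann)
        stats.n_annotations += len(obs_annotations)

    registry = TrickyRegistry()
    for header in cfg.organ_systems:
        registry.register(header, _tricky_examples_for(header, ontology, rng))
    registry.default = registry.by_header[cfg.organ_systems[0].upper()]

    return SyntheticCorpus(observations, annotations, registry, negatives,
                           list(ontology), stats)
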