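"""Two-step dictionary normalization of extracted findings to HPO concepts.

The dictionary maps fully normalized term keys (case-folded, edge-punctuation
stripped, Porter-stemmed, whitespace-collapsed) to HPO IDs.  Keys come from
three sources: HPO preferred terms, HPO synonyms, and annotated surface forms
from the training corpus.  A user-supplied exclusion set drops concepts that
should never be predicted (modifier concepts, unobservable concepts).

Normalization of one prediction proceeds in two steps: first the observed
term — the entity exactly as it appears in the text — is looked up; on a
miss, the model-proposed preferred term is looked up.  The observed-only
mode disables the second step, trading recall for precision (the model's
preferred-term guesses can introduce false concepts).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable

from .corpus_io import OntologyTerm
from .response_parser import EntityPrediction
from .stemming import porter_stem

logger = logging.getLogger(__name__)


class KeySource(str, Enum):
    """Provenance of a dictionary entry, in increasing precedence order."""

    HPO_SYNONYM = "hpo_synonym"
    HPO_PREFERRED = "hpo_preferred"
    TRAINING_SURFACE = "training_surface"


_PRECEDENCE = {
    KeySource.HPO_SYNONYM: 0,
    KeySource.HPO_PREFERRED: 1,
    KeySource.TRAINING_SURFACE: 2,
}

_EDGE_PUNCT = re.compile(r"^\W+|\W+$")


def normalize_key(term: str, stemmer: Callable[[str], str] = porter_stem) -> str:
    """Build the dictionary key for a term.

    Case-fold, split on whitespace, strip punctuation at token edges, stem
    each token, re-join with single spaces.  "Excess nuchal skin" and
    "excess nuchal skin" share a key; so do "flattened midface" and
    "flatten midface".
    """
    tokens = []
    for raw in term.casefold().split():
        token = _EDGE_PUNCT.sub("", raw)
        if token:
            tokens.append(stemmer(token))
    return " ".join(tokens)


@dataclass
class TermDictionary:
    """Normalized-key -> (HPO ID, source) map with an ID exclusion set."""

    entries: dict[str, tuple[str, KeySource]] = field(default_factory=dict)
    exclusions: frozenset[str] = frozenset()
    stemmer: Callable[[str], str] = porter_stem

    def add(self, term: str, hpo_id: str, source: KeySource) -> None:
        """Insert one term; excluded IDs are dropped, key collisions are
        resolved by source precedence (training surface > preferred >
        synonym; later same-precedence entries win, logged)."""
        if hpo_id in self.exclusions:
            return
        key = normalize_key(term, self.stemmer)
        if not key:
            return
        current = self.entries.get(key)
        if current is not None:
            cur_id, cur_source = current
            if _PRECEDENCE[source] < _PRECEDENCE[cur_source]:
                return
            if cur_id != hpo_id:
                logger.info(
                    "dictionary collision on key %r: %s (%s) replaces %s (%s)",
                    key, hpo_id, source.value, cur_id, cur_source.value)
        self.entries[key] = (hpo_id, source)

    def lookup(self, term: str) -> str | None:
        entry = self.entries.get(normalize_key(term, self.stemmer))
        return entry[0] if entry else None

    def __len__(self) -> int:
        return len(self.entries)

    def dump_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("key\thpo_id\tsource\n")
            for key in sorted(self.entries):
                hpo_id, source = self.entries[key]
                handle.write(f"{key}\t{hpo_id}\t{source.value}\n")


def build_dictionary(
    terms: Iterable[OntologyTerm],
    training: Iterable[tuple[str, str]] = (),
    exclusions: Iterable[str] = (),
    stemmer: Callable[[str], str] = porter_stem,
) -> TermDictionary:
    """Build the matching dictionary from ontology terms, training-corpus
    (surface form, HPO ID) pairs, and an excluded-ID set."""
    dictionary = TermDictionary(exclusions=frozenset(exclusions), stemmer=stemmer)
    for term in terms:
        for synonym in term.synonyms:
            dictionary.add(synonym, term.hpo_id, KeySource.HPO_SYNONYM)
    for term in terms:
        dictionary.add(term.preferred_term, term.hpo_id, KeySource.HPO_PREFERRED)
    for surface, hpo_id in training:
        dictionary.add(surface, hpo_id, KeySource.TRAINING_SURFACE)
    return dictionary


def read_exclusions(path: str | Path) -> frozenset[str]:
    """Read an exclusion list: one HPO ID per line, '#' comments allowed."""
    ids = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line)
    return frozenset(ids)


class NormalizationMode(str, Enum):
    OBSERVED_AND_PREFERRED = "observed_and_preferred"
    OBSERVED_ONLY = "observed_only"


class NormalizationStep(str, Enum):
    OBSERVED = "observed"
    PREFERRED = "preferred"
    NONE = "none"


@dataclass(frozen=True)
class NormalizationResult:
    hpo_id: str | None
    step: NormalizationStep

    def __post_init__(self) -> None:
        if (self.hpo_id is None) != (self.step is NormalizationStep.NONE):
            raise ValueError("hpo_id must be absent exactly when step is none")


def normalize_entity(
    pred: EntityPrediction,
    dictionary: TermDictionary,
    mode: NormalizationMode = NormalizationMode.OBSERVED_AND_PREFERRED,
) -> NormalizationResult:
    """Resolve one prediction to an HPO concept, or fail.

    Step 1 looks up the observed term (skipped for parser-discarded
    predictions, which have no usable surface form); step 2 looks up the
    model's preferred term unless the mode disables it.  A miss in both
    steps records no concept.
    """
    if not pred.discarded and pred.observed_term:
        hpo_id = dictionary.lookup(pred.observed_term)
        if hpo_id is not None:
            return NormalizationResult(hpo_id, NormalizationStep.OBSERVED)
    if mode is NormalizationMode.OBSERVED_AND_PREFERRED and pred.preferred_term:
        hpo_id = dictionary.lookup(pred.preferred_term)
        if hpo_id is not None:
            return NormalizationResult(hpo_id, NormalizationStep.PREFERRED)
    return NormalizationResult(None, NormalizationStep.NONE)
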