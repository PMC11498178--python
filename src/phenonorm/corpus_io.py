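"""Corpus and ontology I/O.

Observations are short organ-system examination texts ("EYES: partial
synophrys, long lashes, horizontal slant"), each carrying zero or more gold
finding annotations: an HPO concept ID, a possibly discontinuous character
span set, and a polarity (abnormal "-" vs normal "X").  Corpora travel as
tab-separated tables with one row per (observation, finding) pair; empty
observations appear as a single row whose annotation fields hold the
missing-value token.

Offsets are 0-based with an exclusive end, the only convention under which
the printed span "14-23" selects "synophrys" in the example above.  Span
strings use en-dash-separated "start–end" pairs, disjoint segments joined by
", "; both the en dash and the ASCII hyphen are accepted on read, the en
dash is emitted on write.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, TextIO

EN_DASH = "–"
MISSING = "NA"

HPO_ID_RE = re.compile(r"^HP:\d{7}$")


class Polarity(str, Enum):
    ABNORMAL = "abnormal"
    NORMAL = "normal"

    @classmethod
    def from_marker(cls, marker: str) -> "Polarity":
        """Map the corpus polarity markers: "X" = normal, "-"/en dash = abnormal."""
        marker = marker.strip()
        if marker.upper() == "X":
            return cls.NORMAL
        if marker in {"-", EN_DASH, "—"}:
            return cls.ABNORMAL
        raise CorpusFormatError(f"unrecognized polarity marker {marker!r}")

    def to_marker(self) -> str:
        return "X" if self is Polarity.NORMAL else EN_DASH


class CorpusFormatError(ValueError):
    """A malformed record in a corpus or ontology file."""


@dataclass(frozen=True)
class SpanSet:
    """An ordered set of non-overlapping character segments.

    Each segment is (start, end), 0-based, end-exclusive.  A discontinuous
    entity such as "[normal] lips, [tongue]" owns two segments.
    """

    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.segments:
            if start >= end:
                raise ValueError(f"empty or inverted segment ({start}, {end})")
            if start < prev_end:
                raise ValueError(f"overlapping/unsorted segments in {self.segments}")
            if start < 0:
                raise ValueError(f"negative offset in {self.segments}")
            prev_end = end

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    def extract(self, text: str) -> str:
        """Surface form: segment substrings joined by single spaces."""
        return " ".join(text[s:e] for s, e in self.segments)

    def valid_for(self, text: str) -> bool:
        return all(0 <= s < e <= len(text) for s, e in self.segments)


def parse_spans(spec: str) -> SpanSet:
    """Parse a span string like ``"7–13, 20–26"`` (en dash or hyphen)."""
    spec = spec.strip()
    if not spec:
        return SpanSet(())
    segments = []
    for part in spec.split(","):
        part = part.strip().replace(EN_DASH, "-")
        m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", part)
        if m is None:
            raise CorpusFormatError(f"malformed span segment {part!r} in {spec!r}")
        start, end = int(m.group(1)), int(m.group(2))
        if start >= end:
            raise CorpusFormatError(f"span start >= end in segment {part!r}")
        segments.append((start, end))
    try:
        return SpanSet(tuple(segments))
    except ValueError as exc:
        raise CorpusFormatError(str(exc)) from exc


def serialize_spans(spans: SpanSet) -> str:
    """Inverse of :func:`parse_spans`; emits the en-dash rendering."""
    return ", ".join(f"{s}{EN_DASH}{e}" for s, e in spans.segments)


@dataclass(frozen=True)
class Observation:
    """One organ-system examination text."""

    id: str
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("observation text must be non-empty")

    @property
    def organ_header(self) -> str:
        """Upper-cased text before the first colon; "" when no colon exists."""
        head, sep, _ = self.text.partition(":")
        return head.upper() if sep else ""


@dataclass(frozen=True)
class FindingAnnotation:
    """A gold finding: HPO concept, span set, polarity, on one observation."""

    observation_id: str
    hpo_id: str
    spans: SpanSet
    polarity: Polarity = Polarity.ABNORMAL

    def __post_init__(self) -> None:
        if not HPO_ID_RE.match(self.hpo_id):
            raise ValueError(f"invalid HPO ID {self.hpo_id!r}")


@dataclass(frozen=True)
class OntologyTerm:
    """An HPO concept: ID, preferred term, synonyms."""

    hpo_id: str
    preferred_term: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.preferred_term:
            raise ValueError("preferred_term must be non-empty")


@dataclass(frozen=True)
class CorpusDialect:
    """Column layout of the tabular corpus format.

    The default order matches the shared-task rendering: observation ID,
    text, HPO ID, spans, polarity.  Real task files with other layouts are
    adapted by renaming here, not by code changes.
    """

    id_col: str = "Observation ID"
    text_col: str = "Text"
    hpo_col: str = "HPO ID"
    spans_col: str = "Spans"
    polarity_col: str = "Polarity"
    delimiter: str = "\t"

    @property
    def columns(self) -> tuple[str, ...]:
        return (self.id_col, self.text_col, self.hpo_col,
                self.spans_col, self.polarity_col)


def read_annotated_corpus(
    path: str | Path | TextIO,
    dialect: CorpusDialect | None = None,
) -> tuple[list[Observation], list[FindingAnnotation]]:
    """Read observations and gold annotations from a tabular corpus file.

    Rows whose HPO-ID field is the missing-value token ("NA" or empty)
    contribute an observation but no annotation.  Duplicate
    (id, hpo_id, spans) triples are deduplicated with a warning; malformed
    span strings raise :class:`CorpusFormatError` naming the row.
    """
    dialect = dialect or CorpusDialect()
    if isinstance(path, (str, Path)):
        handle: TextIO = open(path, encoding="utf-8", newline="")
        close = True
    else:
        handle, close = path, False
    try:
        reader = csv.DictReader(handle, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            return [], []
        missing_cols = set(dialect.columns) - set(reader.fieldnames)
        if missing_cols:
            raise CorpusFormatError(f"corpus file lacks columns {sorted(missing_cols)}")

        observations: dict[str, Observation] = {}
        annotations: list[FindingAnnotation] = []
        seen: set[tuple[str, str, tuple]] = set()
        for rownum, row in enumerate(reader, start=2):
            obs_id = (row[dialect.id_col] or "").strip()
            text = row[dialect.text_col] or ""
            if not obs_id or not text:
                raise CorpusFormatError(f"row {rownum}: missing observation id or text")
            existing = observations.get(obs_id)
            if existing is None:
                observations[obs_id] = Observation(obs_id, text)
            elif existing.text != text:
                raise CorpusFormatError(
                    f"row {rownum}: observation {obs_id} has conflicting texts")

            hpo = (row[dialect.hpo_col] or "").strip()
            if not hpo or hpo.upper() == MISSING:
                continue
            try:
                spans = parse_spans(row[dialect.spans_col] or "")
                polarity = Polarity.from_marker(row[dialect.polarity_col] or "")
                ann = FindingAnnotation(obs_id, hpo, spans, polarity)
            except (CorpusFormatError, ValueError) as exc:
                raise CorpusFormatError(f"row {rownum}: {exc}") from exc
            if not spans.valid_for(text):
                raise CorpusFormatError(
                    f"row {rownum}: spans {serialize_spans(spans)} exceed text bounds")
            key = (obs_id, hpo, spans.segments)
            if key in seen:
                warnings.warn(f"row {rownum}: duplicate annotation {key}, dropped")
                continue
            seen.add(key)
            annotations.append(ann)
        return list(observations.values()), annotations
    finally:
        if close:
            handle.close()


def write_annotated_corpus(
    path: str | Path | TextIO,
    observations: Sequence[Observation],
    annotations: Sequence[FindingAnnotation],
    dialect: CorpusDialect | None = None,
) -> None:
    """Inverse of :func:`read_annotated_corpus` (same dialect, NA for empties)."""
    dialect = dialect or CorpusDialect()
    by_obs: dict[str, list[FindingAnnotation]] = {o.id: [] for o in observations}
    for ann in annotations:
        if ann.observation_id not in by_obs:
            raise CorpusFormatError(
                f"annotation references unknown observation {ann.observation_id}")
        by_obs[ann.observation_id].append(ann)

    if isinstance(path, (str, Path)):
        handle: TextIO = open(path, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle, close = path, False
    try:
        writer = csv.writer(handle, delimiter=dialect.delimiter,
                            lineterminator="\n")
        writer.writerow(dialect.columns)
        for obs in observations:
            anns = by_obs[obs.id]
            if not anns:
                writer.writerow([obs.id, obs.text, MISSING, MISSING, MISSING])
            for ann in anns:
                writer.writerow([obs.id, obs.text, ann.hpo_id,
                                 serialize_spans(ann.spans),
                                 ann.polarity.to_marker()])
    finally:
        if close:
            handle.close()


def read_term_table(path: str | Path, format: str = "tsv") -> list[OntologyTerm]:
    """Read an HPO term table as OntologyTerm records.

    ``format="tsv"``: columns hpo_id, preferred_term, then zero or more
    synonym columns (trailing columns may be a single pipe-joined cell).
    ``format="obo-minimal"``: [Term] stanzas with id/name/synonym lines;
    synonym strings are stripped of OBO quoting and scope qualifiers.
    Stanzas lacking an id or name are skipped with a warning.
    """
    if format == "tsv":
        return _read_term_tsv(path)
    if format == "obo-minimal":
        return _read_term_obo(path)
    raise ValueError(f"unknown term-table format {format!r}")


def _read_term_tsv(path: str | Path) -> list[OntologyTerm]:
    terms: list[OntologyTerm] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        for rownum, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                warnings.warn(f"term row {rownum} lacks id or name, skipped")
                continue
            synonyms = []
            for cell in row[2:]:
                synonyms.extend(s.strip() for s in cell.split("|") if s.strip())
            terms.append(OntologyTerm(row[0].strip(), row[1].strip(),
                                      tuple(synonyms)))
    return terms


def _read_term_obo(path: str | Path) -> list[OntologyTerm]:
    import obonet

    graph = obonet.read_obo(path, ignore_obsolete=False)
    terms: list[OntologyTerm] = []
    syn_re = re.compile(r'"([^"]*)"')
    for node, data in graph.nodes(data=True):
        name = data.get("name")
        if not name:
            warnings.warn(f"stanza {node} lacks a name, skipped")
            continue
        synonyms = []
        for syn in data.get("synonym", []):
            m = syn_re.search(syn)
            synonyms.append(m.group(1) if m else syn)
        terms.append(OntologyTerm(node, name, tuple(synonyms)))
    terms.sort(key=lambda t: t.hpo_id)
    return terms


def write_term_table(path: str | Path, terms: Iterable[OntologyTerm]) -> None:
    """Write terms in the TSV layout :func:`read_term_table` accepts."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["hpo_id", "preferred_term", "synonyms"])
        for term in terms:
            writer.writerow([term.hpo_id, term.preferred_term,
                             "|".join(term.synonyms)])


def write_term_obo(path: str | Path, terms: Iterable[OntologyTerm]) -> None:
    """Write a minimal OBO file (id/name/synonym stanzas)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("format-version: 1.2\nontology: hp\n")
        for term in terms:
            handle.write(f"\n[Term]\nid: {term.hpo_id}\nname: {term.preferred_term}\n")
            for syn in term.synonyms:
                handle.write(f'synonym: "{syn}" EXACT []\n')
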