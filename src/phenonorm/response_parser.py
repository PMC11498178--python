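"""Parsing of model responses: entity tables and marked-text span recovery.

The model reports each entity by echoing the observation text with the
entity's segments wrapped in square brackets.  Offsets are recovered by
locating the brackets; the unmarked echo must reproduce the original text,
otherwise the offsets are meaningless (models occasionally "fix" typos or
append stray characters — e.g. echoing "HEAD: +cephalohematoma" as
"HEAD: +cephalohematoma+").  Such predictions are discarded rather than
repaired, retained in the output with a reason for error analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum

from .corpus_io import SpanSet
from .prompting import TABLE_HEADER

logger = logging.getLogger(__name__)


class DiscardReason(str, Enum):
    NONE = "none"
    TEXT_MISMATCH = "text_mismatch"
    OUT_OF_BOUNDS = "out_of_bounds"
    UNBALANCED_BRACKETS = "unbalanced_brackets"
    NO_BRACKETS = "no_brackets"


class BracketError(ValueError):
    """Unbalanced or nested square brackets in marked text."""


@dataclass(frozen=True)
class EntityPrediction:
    """One parsed response row.

    ``observed_term`` is the entity's surface form: span substrings joined
    by single spaces.  Discarded predictions carry no spans and an empty
    observed term, but keep the preferred term (normalization may still
    succeed on it).
    """

    preferred_term: str
    observed_term: str
    spans: SpanSet | None
    discard_reason: DiscardReason = DiscardReason.NONE

    @property
    def discarded(self) -> bool:
        return self.discard_reason is not DiscardReason.NONE


def recover_spans(marked: str) -> tuple[str, SpanSet]:
    """Invert the marking: strip brackets, return (unmarked text, spans).

    Each bracketed run becomes one segment with offsets into the unmarked
    string; disjoint runs are supported.  Raises :class:`BracketError` on
    unbalanced or nested brackets.  Empty bracket pairs "[]" mark nothing
    and are dropped.
    """
    out: list[str] = []
    segments: list[tuple[int, int]] = []
    open_at: int | None = None
    pos = 0
    for ch in marked:
        if ch == "[":
            if open_at is not None:
                raise BracketError(f"nested '[' in {marked!r}")
            open_at = pos
        elif ch == "]":
            if open_at is None:
                raise BracketError(f"unmatched ']' in {marked!r}")
            if pos > open_at:
                segments.append((open_at, pos))
            open_at = None
        else:
            out.append(ch)
            pos += 1
    if open_at is not None:
        raise BracketError(f"unclosed '[' in {marked!r}")
    return "".join(out), SpanSet(tuple(segments))


_WS_RUN = re.compile(r"\s+")


def _collapse_ws(text: str) -> str:
    return _WS_RUN.sub(" ", text).strip()


def _remap_ws(spans: SpanSet, source: str, target: str) -> SpanSet | None:
    """Remap offsets from ``source`` onto ``target`` when the two differ only
    in whitespace runs; None when a segment boundary cannot be placed."""
    mapping: dict[int, int] = {}  # source char index -> target char index
    i = j = 0
    while i < len(source) and j < len(target):
        if source[i] == target[j]:
            mapping[i] = j
            i += 1
            j += 1
        elif source[i].isspace():
            i += 1
        elif target[j].isspace():
            j += 1
        else:  # non-whitespace difference; caller already checked, be safe
            return None
    segments = []
    for start, end in spans.segments:
        # trim whitespace that has no image in the target
        while start < end and start not in mapping:
            start += 1
        while end > start and (end - 1) not in mapping:
            end -= 1
        if start >= end:
            return None
        segments.append((mapping[start], mapping[end - 1] + 1))
    try:
        return SpanSet(tuple(segments))
    except ValueError:
        return None


def _parse_row(preferred: str, marked: str, original_text: str) -> EntityPrediction:
    try:
        unmarked, spans = recover_spans(marked)
    except BracketError:
        return EntityPrediction(preferred, "", None, DiscardReason.UNBALANCED_BRACKETS)

    if unmarked != original_text:
        if _collapse_ws(unmarked) != _collapse_ws(original_text):
            return EntityPrediction(preferred, "", None, DiscardReason.TEXT_MISMATCH)
        # whitespace-only drift: remap offsets onto the original
        remapped = _remap_ws(spans, unmarked, original_text)
        if remapped is None:
            return EntityPrediction(preferred, "", None, DiscardReason.TEXT_MISMATCH)
        spans = remapped

    if len(spans) == 0:
        return EntityPrediction(preferred, "", None, DiscardReason.NO_BRACKETS)
    if not spans.valid_for(original_text):
        return EntityPrediction(preferred, "", None, DiscardReason.OUT_OF_BOUNDS)
    return EntityPrediction(preferred, spans.extract(original_text), spans)


_SEPARATOR_ROW = re.compile(r"^[\s|:\-]+$")
_HEADER_CELLS = [c.strip().lower() for c in TABLE_HEADER.strip("|").split("|")]


def parse_entity_table(response: str, original_text: str) -> list[EntityPrediction]:
    """Parse a pipe-delimited response table into predictions.

    ``original_text`` must be pre-processed (no square brackets of its own).
    Header and markdown separator lines are skipped; leading/trailing pipes
    are optional.  Rows whose marked text fails span recovery are retained
    with a discard reason but carry no spans.  A response with no
    recognizable table rows yields an empty list.
    """
    predictions: list[EntityPrediction] = []
    saw_table = False
    for line in response.splitlines():
        line = line.strip()
        if not line or "|" not in line:
            continue
        if _SEPARATOR_ROW.match(line):
            continue
        cells = [c.strip() for c in line.strip("|").split("|")]
        if [c.lower() for c in cells] == _HEADER_CELLS:
            saw_table = True
            continue
        if len(cells) < 2:
            logger.info("skipping malformed table row %r", line)
            continue
        saw_table = True
        pred = _parse_row(cells[0], cells[1], original_text)
        if pred.discarded:
            logger.info("discarded prediction %r: %s",
                        cells[0], pred.discard_reason.value)
        predictions.append(pred)
    if not saw_table and response.strip():
        logger.warning("response contains no recognizable entity table")
    return predictions
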