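"""Chat-prompt construction and the marked-text entity encoding.

The LLM is never asked for character offsets (generative models hallucinate
them) nor HPO IDs (they hallucinate those too).  Instead each extracted
entity is reported as a two-column table row: the ontology's preferred term,
and the full observation text with the entity's span(s) wrapped in square
brackets.  Offsets are recovered downstream by locating the brackets.  To
keep brackets unambiguous, input text is pre-processed by replacing any
pre-existing square brackets with round ones; the replacement is 1:1 so
gold offsets stay valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

from .corpus_io import FindingAnnotation, Observation, SpanSet

TABLE_HEADER = "| HPO Preferred Term | Marked Observation |"

#: Default system instruction for the extraction task.
DEFAULT_SYSTEM_TEXT = (
    "Extract Human Phenotype Ontology (HPO) concepts from the given text of "
    "a physical examination note into a table containing standard HPO "
    "preferred term and marked original text with square brackets "
    "surrounding the words associated with the HPO term."
)


class Role(str, Enum):
    SYSTEM = "system"
    USER = "user"
    ASSISTANT = "assistant"


@dataclass(frozen=True)
class ChatMessage:
    role: Role
    content: str

    def __post_init__(self) -> None:
        if self.role in (Role.SYSTEM, Role.USER) and not self.content:
            raise ValueError(f"{self.role.value} message content must be non-empty")


@dataclass(frozen=True)
class Prompt:
    """An ordered chat: one system message first, then (user, assistant) pairs;
    at inference the final message is the bare user query."""

    messages: tuple[ChatMessage, ...]

    def __post_init__(self) -> None:
        if not self.messages or self.messages[0].role is not Role.SYSTEM:
            raise ValueError("prompt must start with a system message")
        if any(m.role is Role.SYSTEM for m in self.messages[1:]):
            raise ValueError("prompt must contain exactly one system message")
        expect_user = True
        for msg in self.messages[1:]:
            want = Role.USER if expect_user else Role.ASSISTANT
            if msg.role is not want:
                raise ValueError("messages after system must alternate user/assistant")
            expect_user = not expect_user

    @property
    def final_role(self) -> Role:
        return self.messages[-1].role


@dataclass(frozen=True)
class EntityTableRow:
    preferred_term: str
    marked_text: str


def preprocess_text(text: str) -> str:
    """Replace pre-existing square brackets with round ones (length-stable)."""
    return text.replace("[", "(").replace("]", ")")


def mark_text(text: str, spans: SpanSet) -> str:
    """Wrap each span segment of ``text`` in square brackets.

    ``text`` must already be pre-processed; insertions run right-to-left so
    earlier offsets are unaffected.  Disjoint segments are bracketed
    separately: ("EARS: Low-set left ear", [(6,13),(19,22)]) ->
    "EARS: [Low-set] left [ear]".
    """
    if not spans.valid_for(text):
        raise ValueError(f"spans {spans.segments} invalid for text of length {len(text)}")
    out = text
    for start, end in reversed(spans.segments):
        out = out[:start] + "[" + out[start:end] + "]" + out[end:]
    return out


def render_entity_table(rows: Sequence[EntityTableRow]) -> str:
    """Render rows as the pipe-delimited response table.

    Zero rows renders the header alone — the parser reads "no data rows" as
    "no entities", which is the convention negative examples teach.  A "|"
    inside a cell would corrupt the table, so it is replaced by "/" with a
    warning.
    """
    lines = [TABLE_HEADER]
    for row in rows:
        cells = []
        for cell in (row.preferred_term, row.marked_text):
            if "|" in cell:
                warnings.warn(f"pipe character in table cell {cell!r} replaced by '/'")
                cell = cell.replace("|", "/")
            cells.append(cell)
        lines.append(f"| {cells[0]} | {cells[1]} |")
    return "\n".join(lines)


def annotations_to_rows(
    obs: Observation,
    annotations: Iterable[FindingAnnotation],
    preferred_lookup: Mapping[str, str] | Callable[[str], str],
) -> list[EntityTableRow]:
    """Render gold annotations of one observation as entity-table rows.

    Rows are ordered by ascending first-segment start for deterministic
    serialization.  ``preferred_lookup`` maps HPO ID -> preferred term and
    must cover every annotated ID.
    """
    lookup = preferred_lookup.__getitem__ if isinstance(preferred_lookup, Mapping) \
        else preferred_lookup
    text = preprocess_text(obs.text)
    rows = []
    for ann in sorted(annotations, key=lambda a: a.spans.segments):
        try:
            preferred = lookup(ann.hpo_id)
        except KeyError:
            raise KeyError(f"no preferred term known for {ann.hpo_id}") from None
        rows.append(EntityTableRow(preferred, mark_text(text, ann.spans)))
    return rows


def build_inference_prompt(
    system_text: str,
    fewshot: Sequence[tuple[str, str]],
    query_text: str,
) -> Prompt:
    """System message, then few-shot (user, assistant) pairs in order, then
    the final user query.  ``query_text`` must be pre-processed."""
    messages = [ChatMessage(Role.SYSTEM, system_text)]
    for user_content, assistant_content in fewshot:
        messages.append(ChatMessage(Role.USER, user_content))
        messages.append(ChatMessage(Role.ASSISTANT, assistant_content))
    messages.append(ChatMessage(Role.USER, query_text))
    return Prompt(tuple(messages))


def build_training_record(
    obs: Observation,
    annotations: Sequence[FindingAnnotation],
    preferred_lookup: Mapping[str, str] | Callable[[str], str],
    system_text: str = DEFAULT_SYSTEM_TEXT,
) -> Prompt:
    """One 3-message fine-tuning record per observation:
    system / user(pre-processed text) / assistant(entity table)."""
    rows = annotations_to_rows(obs, annotations, preferred_lookup)
    return Prompt((
        ChatMessage(Role.SYSTEM, system_text),
        ChatMessage(Role.USER, preprocess_text(obs.text)),
        ChatMessage(Role.ASSISTANT, render_entity_table(rows)),
    ))
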