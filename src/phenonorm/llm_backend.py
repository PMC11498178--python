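"""Chat-completion backend contract, deterministic mocks, fine-tune export.

The pipeline treats the language model as a black box behind a one-method
protocol: submit a prompt ending in a user message, receive the assistant
content.  For offline development and testing, replay backends answer from a
gold index (final user text -> gold entity table), optionally corrupting the
response in the ways real models fail: silently "fixing" a typo in the
echoed text, appending a stray character, or dropping rows.

Fine-tuning data export writes the standard chat JSON Lines format (one
``{"messages": [...]}`` object per observation); actually launching a
remote fine-tune job is a vendor-side operation exposed only as a stub.
"""

from __future__ import annotations

import json
import logging
import random
import time
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .prompting import TABLE_HEADER, ChatMessage, Prompt, Role

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BackendResponse:
    content: str
    meta: dict = field(default_factory=dict)


class TransportError(RuntimeError):
    """Retryable transport failure (timeout, connection reset, 5xx)."""


class Backend:
    """Backend contract: ``complete`` one prompt into an assistant message."""

    def complete(self, prompt: Prompt) -> BackendResponse:
        raise NotImplementedError


class Corruption(str, Enum):
    NONE = "none"
    FIX_TYPO = "fix_typo"
    BRACKET_APPEND = "bracket_append"
    DROP_ROWS = "drop_rows"


class MockReplayBackend(Backend):
    """Replay gold responses, optionally corrupted, fully deterministically.

    ``gold_index`` maps the final user text to its gold entity-table string.
    Unknown texts get a header-only (no entities) response.  Corruption is
    seeded: the same (seed, prompt) pair always yields the same response.
    """

    def __init__(
        self,
        gold_index: Mapping[str, str],
        corruption: Corruption = Corruption.NONE,
        seed: int = 0,
    ) -> None:
        self.gold_index = gold_index
        self.corruption = corruption
        self.seed = seed

    def complete(self, prompt: Prompt) -> BackendResponse:
        if prompt.final_role is not Role.USER:
            raise ValueError("prompt must end in a user message")
        query = prompt.messages[-1].content
        gold = self.gold_index.get(query)
        if gold is None:
            return BackendResponse(TABLE_HEADER, {"model": "mock-replay",
                                                  "replay": "miss"})
        content = self._corrupt(gold, query)
        return BackendResponse(content, {"model": "mock-replay",
                                         "corruption": self.corruption.value})

    def _rng(self, query: str) -> random.Random:
        return random.Random(f"{self.seed}:{query}")

    def _corrupt(self, gold: str, query: str) -> str:
        if self.corruption is Corruption.NONE:
            return gold
        rng = self._rng(query)
        lines = gold.splitlines()
        header, rows = lines[0], lines[1:]
        if not rows:
            return gold
        if self.corruption is Corruption.DROP_ROWS:
            kept = [row for row in rows if rng.random() >= 0.5]
            return "\n".join([header] + kept)

        idx = rng.randrange(len(rows))
        cells = [c.strip() for c in rows[idx].strip("|").split("|")]
        preferred, marked = cells[0], cells[1]
        if self.corruption is Corruption.BRACKET_APPEND:
            # stray trailing character inside the marked-text cell, as when a
            # model echoes "HEAD: +cephalohematoma" as "HEAD: +cephalohematoma+"
            marked = marked + rng.choice("+*.;")
        elif self.corruption is Corruption.FIX_TYPO:
            positions = [i for i, ch in enumerate(marked)
                         if ch not in "[]" and ch.isalpha()]
            if positions:
                pos = rng.choice(positions)
                replacement = rng.choice(
                    [c for c in "abcdefghijklmnopqrstuvwxyz"
                     if c != marked[pos].lower()])
                marked = marked[:pos] + replacement + marked[pos + 1:]
        rows[idx] = f"| {preferred} | {marked} |"
        return "\n".join([header] + rows)


class CallableBackend(Backend):
    """Adapt any ``prompt -> str`` callable to the backend contract."""

    def __init__(self, fn: Callable[[Prompt], str]) -> None:
        self.fn = fn

    def complete(self, prompt: Prompt) -> BackendResponse:
        return BackendResponse(self.fn(prompt), {"model": "callable"})


class ChatAPIBackend(Backend):
    """Thin HTTP adapter for the common chat-completion API shape.

    Sends ``{"model", "messages", "temperature"}`` and reads the first
    choice's message content.  Temperature defaults to 0 for
    reproducibility.  Requires network access and credentials; never used
    by the offline pipeline or tests.
    """

    def __init__(self, base_url: str, model: str, api_key: str = "",
                 temperature: float = 0.0, timeout: float = 60.0) -> None:
        self.base_url = base_url.rstrip("/")
        self.model = model
        self.api_key = api_key
        self.temperature = temperature
        self.timeout = timeout

    def complete(self, prompt: Prompt) -> BackendResponse:
        import urllib.error
        import urllib.request

        payload = json.dumps({
            "model": self.model,
            "messages": [{"role": m.role.value, "content": m.content}
                         for m in prompt.messages],
            "temperature": self.temperature,
        }).encode()
        request = urllib.request.Request(
            f"{self.base_url}/chat/completions", data=payload,
            headers={"Content-Type": "application/json",
                     "Authorization": f"Bearer {self.api_key}"})
        try:
            with urllib.request.urlopen(request, timeout=self.timeout) as resp:
                body = json.loads(resp.read().decode())
        except (urllib.error.URLError, TimeoutError, OSError) as exc:
            raise TransportError(str(exc)) from exc
        choice = body["choices"][0]["message"]["content"]
        return BackendResponse(choice, {"model": body.get("model", self.model),
                                        "usage": body.get("usage", {})})


@dataclass(frozen=True)
class RetryPolicy:
    attempts: int = 3
    base_delay: float = 1.0  # seconds; doubles per retry

    def delays(self):
        for i in range(self.attempts - 1):
            yield self.base_delay * (2 ** i)


def complete_with_retry(
    backend: Backend,
    prompt: Prompt,
    policy: RetryPolicy = RetryPolicy(),
    sleep: Callable[[float], None] = time.sleep,
) -> BackendResponse:
    """Call the backend, retrying transport errors with exponential backoff;
    re-raises after the final attempt."""
    delays = list(policy.delays()) + [None]
    for delay in delays:
        try:
            return backend.complete(prompt)
        except TransportError:
            if delay is None:
                raise
            logger.warning("backend transport error, retrying in %.1fs", delay)
            sleep(delay)
    raise AssertionError("unreachable")


def export_finetune_dataset(records: Sequence[Prompt],
                            path: str | Path) -> None:
    """Write fine-tuning records as chat JSON Lines.

    Every record must be a 3-message system/user/assistant prompt; each line
    is ``{"messages": [{"role": ..., "content": ...}, ...]}``, UTF-8.
    """
    roles = (Role.SYSTEM, Role.USER, Role.ASSISTANT)
    with open(path, "w", encoding="utf-8") as handle:
        for i, record in enumerate(records):
            if tuple(m.role for m in record.messages) != roles:
                raise ValueError(
                    f"record {i}: expected system/user/assistant messages, "
                    f"got {[m.role.value for m in record.messages]}")
            line = json.dumps(
                {"messages": [{"role": m.role.value, "content": m.content}
                              for m in record.messages]},
                ensure_ascii=False)
            handle.write(line + "\n")


def import_finetune_dataset(path: str | Path) -> list[Prompt]:
    """Inverse of :func:`export_finetune_dataset` (round-trips exactly)."""
    prompts = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if not line.strip():
                continue
            obj = json.loads(line)
            prompts.append(Prompt(tuple(
                ChatMessage(Role(m["role"]), m["content"])
                for m in obj["messages"])))
    return prompts


def initiate_finetune_job(dataset_path: str | Path, model: str) -> str:
    """Interface stub for launching a remote fine-tuning job.

    Uploading data and training happen on the vendor's side; this package
    only prepares the dataset.  Raises until wired to a concrete provider.
    """
    raise NotImplementedError(
        "remote fine-tuning is provider-side; export the dataset with "
        "export_finetune_dataset and launch the job with your provider's API")
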