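"""Scoring against gold under the three shared-task settings.

A prediction matches a gold finding only within the same observation and
with the same HPO concept; the settings differ in the span condition:

* ``strict`` — identical span sets;
* ``overlapping`` — at least one shared character between any segments;
* ``normalization_only`` — no span condition (concept ID alone).

Matching is one-to-one per observation.  Within each (observation, concept)
group a maximum bipartite matching is computed, which makes the counts
invariant to prediction order and monotone in the match relation: since
strict matches are overlapping matches are ID matches, TP(strict) <=
TP(overlapping) <= TP(normalization_only) on identical inputs, and with a
fixed prediction set F1 inherits the ordering.  TP/FP/FN are pooled over the
corpus before computing precision, recall and F1 (micro-averaging).

Predictions that failed to normalize (no concept ID) are excluded from
scoring by default in every setting; ``count_unnormalized_as_fp`` makes the
span settings count them as false positives instead.  Duplicate identical
predictions are deduplicated before scoring.  Predictions whose spans were
discarded by the parser but that still carry a concept ID participate
everywhere: matchable in normalization-only, unmatched (false positive) in
the span settings.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

from .corpus_io import FindingAnnotation, SpanSet


class EvalSetting(str, Enum):
    NORMALIZATION_ONLY = "normalization_only"
    STRICT = "strict"
    OVERLAPPING = "overlapping"


@dataclass(frozen=True)
class ScoredPrediction:
    """A normalized prediction ready for scoring: observation, concept, and
    the recovered span set (None when the parser discarded the spans)."""

    observation_id: str
    hpo_id: str | None
    spans: SpanSet | None


@dataclass(frozen=True)
class EvalReport:
    setting: EvalSetting
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {"setting": self.setting.value, "tp": self.tp, "fp": self.fp,
                "fn": self.fn, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def _spans_overlap(a: SpanSet, b: SpanSet) -> bool:
    return any(sa < eb and sb < ea
               for sa, ea in a.segments for sb, eb in b.segments)


def _match_condition(pred: ScoredPrediction, gold: FindingAnnotation,
                     setting: EvalSetting) -> bool:
    if setting is EvalSetting.NORMALIZATION_ONLY:
        return True
    if pred.spans is None:
        return False
    if setting is EvalSetting.STRICT:
        return pred.spans.segments == gold.spans.segments
    return _spans_overlap(pred.spans, gold.spans)


def _max_matching(preds: Sequence[ScoredPrediction],
                  golds: Sequence[FindingAnnotation],
                  setting: EvalSetting) -> int:
    """Maximum bipartite matching size via augmenting paths (groups are tiny)."""
    edges = [[g for g, gold in enumerate(golds)
              if _match_condition(pred, gold, setting)] for pred in preds]
    match_of_gold: dict[int, int] = {}

    def augment(p: int, seen: set[int]) -> bool:
        for g in edges[p]:
            if g in seen:
                continue
            seen.add(g)
            if g not in match_of_gold or augment(match_of_gold[g], seen):
                match_of_gold[g] = p
                return True
        return False

    return sum(augment(p, set()) for p in range(len(preds)))


def evaluate(
    gold: Sequence[FindingAnnotation],
    predictions: Sequence[ScoredPrediction],
    setting: EvalSetting,
    known_observations: set[str] | None = None,
    count_unnormalized_as_fp: bool = False,
) -> EvalReport:
    """Micro-averaged TP/FP/FN and P/R/F1 for one setting.

    ``gold`` should be restricted to abnormal findings (the task scores no
    normal ones).  ``known_observations``, when given, validates that every
    prediction references a known observation.
    """
    if known_observations is not None:
        for pred in predictions:
            if pred.observation_id not in known_observations:
                raise ValueError(f"prediction references unknown observation "
                                 f"{pred.observation_id}")

    deduped: list[ScoredPrediction] = []
    seen = set()
    for pred in predictions:
        key = (pred.observation_id, pred.hpo_id,
               pred.spans.segments if pred.spans is not None else None)
        if key not in seen:
            seen.add(key)
            deduped.append(pred)

    unnormalized = [p for p in deduped if p.hpo_id is None]
    scored = [p for p in deduped if p.hpo_id is not None]

    pred_groups: dict[tuple[str, str], list[ScoredPrediction]] = defaultdict(list)
    for pred in scored:
        pred_groups[(pred.observation_id, pred.hpo_id)].append(pred)
    gold_groups: dict[tuple[str, str], list[FindingAnnotation]] = defaultdict(list)
    for ann in gold:
        gold_groups[(ann.observation_id, ann.hpo_id)].append(ann)

    tp = 0
    for key, preds in pred_groups.items():
        tp += _max_matching(preds, gold_groups.get(key, []), setting)
    fp = len(scored) - tp
    fn = len(gold) - tp
    if count_unnormalized_as_fp and setting is not EvalSetting.NORMALIZATION_ONLY:
        fp += len(unnormalized)
    return EvalReport(setting, tp, fp, fn)


def evaluate_all(
    gold: Sequence[FindingAnnotation],
    predictions: Sequence[ScoredPrediction],
    known_observations: set[str] | None = None,
    count_unnormalized_as_fp: bool = False,
) -> dict[EvalSetting, EvalReport]:
    """Evaluate under all three settings on identical inputs."""
    return {setting: evaluate(gold, predictions, setting, known_observations,
                              count_unnormalized_as_fp)
            for setting in EvalSetting}


def write_report_json(path: str | Path,
                      reports: dict[EvalSetting, EvalReport]) -> None:
    payload = {setting.value: report.as_dict()
               for setting, report in reports.items()}
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
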