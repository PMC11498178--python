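"""Dataset consistency pass: detect and repair annotation inconsistencies.

Shared-task gold annotations drift in two ways.  Span inconsistencies: the
same concept is annotated sometimes with and sometimes without a leading or
trailing modifier ("Prominent [infraorbital creases]" vs "[Prominent
infraorbital creases]"), although the guidelines exclude modifiers.  Concept
inconsistencies: one surface form is mapped to different near-duplicate HPO
concepts across the corpus ("excess nuchal skin" to both HP:0005989 and
HP:0000474).  This module detects both automatically; concept repair can be
automatic (majority vote) or via a reviewed manual map, span repair is
manual-map only.  It also merges co-occurring concept pairs into their
combined concept and drops normal-polarity findings, which the task does not
score.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import FindingAnnotation, Observation, Polarity, SpanSet

logger = logging.getLogger(__name__)

#: Modifier words the annotation guidelines exclude from entity boundaries.
DEFAULT_MODIFIER_LEXICON = (
    "mild", "mildly", "slight", "slightly", "prominent", "partial",
    "partially", "very", "somewhat", "borderline",
)


class InconsistencyKind(str, Enum):
    SPAN = "span"
    CONCEPT = "concept"


@dataclass(frozen=True)
class Variant:
    value: str  # surface form (span kind) or HPO ID (concept kind)
    count: int
    example_observation_id: str


@dataclass(frozen=True)
class InconsistencyReport:
    kind: InconsistencyKind
    key: str  # HPO ID for span kind; case-folded surface for concept kind
    variants: tuple[Variant, ...]

    def __post_init__(self) -> None:
        if len(self.variants) < 2:
            raise ValueError("an inconsistency needs at least two variants")


@dataclass(frozen=True)
class MergeRule:
    """Replace co-occurring source concepts with one combined target concept,
    e.g. low-set ears + posteriorly rotated ears -> low-set and posteriorly
    rotated ears."""

    source_ids: tuple[str, ...]
    target_id: str

    def __post_init__(self) -> None:
        if len(self.source_ids) < 2:
            raise ValueError("a merge rule needs at least two source concepts")
        if self.target_id in self.source_ids:
            raise ValueError("merge target must differ from all sources")


def _surface(ann: FindingAnnotation, texts: Mapping[str, str]) -> str:
    return ann.spans.extract(texts[ann.observation_id])


def _index_texts(observations: Iterable[Observation]) -> dict[str, str]:
    return {obs.id: obs.text for obs in observations}


def _differs_only_by_modifiers(a: str, b: str, modifiers: frozenset[str]) -> bool:
    """True when one token sequence equals the other with leading/trailing
    modifier tokens stripped (in either direction)."""
    ta, tb = a.casefold().split(), b.casefold().split()
    if ta == tb:
        return False
    for longer, shorter in ((ta, tb), (tb, ta)):
        n, m = len(longer), len(shorter)
        if n <= m:
            continue
        for lead in range(n - m + 1):
            if longer[lead:lead + m] != shorter:
                continue
            trimmed = longer[:lead] + longer[lead + m:]
            if trimmed and all(tok in modifiers for tok in trimmed):
                return True
    return False


def detect_span_inconsistencies(
    annotations: Sequence[FindingAnnotation],
    observations: Sequence[Observation],
    modifier_lexicon: Iterable[str] = DEFAULT_MODIFIER_LEXICON,
) -> list[InconsistencyReport]:
    """Report HPO IDs annotated with surface forms that differ only by
    leading/trailing modifier tokens."""
    texts = _index_texts(observations)
    modifiers = frozenset(m.casefold() for m in modifier_lexicon)
    by_id: dict[str, Counter] = defaultdict(Counter)
    example: dict[tuple[str, str], str] = {}
    for ann in annotations:
        surface = _surface(ann, texts)
        by_id[ann.hpo_id][surface] += 1
        example.setdefault((ann.hpo_id, surface), ann.observation_id)

    reports = []
    for hpo_id in sorted(by_id):
        surfaces = by_id[hpo_id]
        involved: set[str] = set()
        forms = sorted(surfaces)
        for i, a in enumerate(forms):
            for b in forms[i + 1:]:
                if _differs_only_by_modifiers(a, b, modifiers):
                    involved.update((a, b))
        if involved:
            variants = tuple(
                Variant(s, surfaces[s], example[(hpo_id, s)])
                for s in sorted(involved, key=lambda s: (-surfaces[s], s)))
            reports.append(InconsistencyReport(InconsistencyKind.SPAN,
                                               hpo_id, variants))
    return reports


def detect_concept_inconsistencies(
    annotations: Sequence[FindingAnnotation],
    observations: Sequence[Observation],
) -> list[InconsistencyReport]:
    """Report case-folded surface forms mapped to two or more HPO IDs,
    variants in descending count order."""
    texts = _index_texts(observations)
    by_surface: dict[str, Counter] = defaultdict(Counter)
    example: dict[tuple[str, str], str] = {}
    for ann in annotations:
        surface = _surface(ann, texts).casefold()
        by_surface[surface][ann.hpo_id] += 1
        example.setdefault((surface, ann.hpo_id), ann.observation_id)

    reports = []
    for surface in sorted(by_surface):
        ids = by_surface[surface]
        if len(ids) < 2:
            continue
        variants = tuple(
            Variant(hpo_id, count, example[(surface, hpo_id)])
            for hpo_id, count in sorted(ids.items(),
                                        key=lambda kv: (-kv[1], kv[0])))
        reports.append(InconsistencyReport(InconsistencyKind.CONCEPT,
                                           surface, variants))
    return reports


class ResolvePolicy(str, Enum):
    MAJORITY = "majority"
    MANUAL_MAP = "manual-map"


def resolve_concept_inconsistencies(
    annotations: Sequence[FindingAnnotation],
    observations: Sequence[Observation],
    reports: Sequence[InconsistencyReport],
    policy: ResolvePolicy = ResolvePolicy.MAJORITY,
    manual_map: Mapping[str, str] | None = None,
) -> tuple[list[FindingAnnotation], list[str]]:
    """Rewrite inconsistently mapped concepts; returns (annotations, flagged).

    Majority policy rewrites every variant of a surface form to its most
    frequent ID; ties are left unchanged and flagged.  Manual-map applies a
    user-supplied case-folded-surface -> ID table.
    """
    texts = _index_texts(observations)
    target_by_surface: dict[str, str] = {}
    flagged: list[str] = []
    for report in reports:
        if report.kind is not InconsistencyKind.CONCEPT:
            continue
        if policy is ResolvePolicy.MANUAL_MAP:
            if manual_map and report.key in manual_map:
                target_by_surface[report.key] = manual_map[report.key]
            else:
                flagged.append(report.key)
        else:
            top, runner_up = report.variants[0], report.variants[1]
            if top.count == runner_up.count:
                flagged.append(report.key)
            else:
                target_by_surface[report.key] = top.value

    updated = []
    for ann in annotations:
        surface = _surface(ann, texts).casefold()
        target = target_by_surface.get(surface)
        if target is not None and target != ann.hpo_id:
            ann = FindingAnnotation(ann.observation_id, target, ann.spans,
                                    ann.polarity)
        updated.append(ann)
    return updated, flagged


def _coalesce(segments: Iterable[tuple[int, int]]) -> SpanSet:
    merged: list[list[int]] = []
    for start, end in sorted(segments):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return SpanSet(tuple((s, e) for s, e in merged))


def apply_merge_rules(
    annotations: Sequence[FindingAnnotation],
    rules: Sequence[MergeRule],
) -> list[FindingAnnotation]:
    """Apply concept merges within each observation.

    When all of a rule's source concepts co-occur in one observation, their
    annotations are replaced by a single target-concept annotation whose
    span set is the union of the sources' segments (coalesced if adjacent or
    overlapping).  The merged annotation takes the position of the first
    source annotation; polarity follows the sources (mixed polarity blocks
    the merge).
    """
    by_obs: dict[str, list[int]] = defaultdict(list)
    for i, ann in enumerate(annotations):
        by_obs[ann.observation_id].append(i)

    drop: set[int] = set()
    replacement: dict[int, FindingAnnotation] = {}
    for rule in rules:
        for obs_id, indices in by_obs.items():
            chosen: list[int] = []
            for source_id in rule.source_ids:
                idx = next((i for i in indices
                            if annotations[i].hpo_id == source_id
                            and i not in drop), None)
                if idx is None:
                    break
                chosen.append(idx)
            else:
                polarities = {annotations[i].polarity for i in chosen}
                if len(polarities) > 1:
                    logger.warning("merge %s skipped in %s: mixed polarity",
                                   rule.target_id, obs_id)
                    continue
                segments = [seg for i in chosen
                            for seg in annotations[i].spans.segments]
                merged = FindingAnnotation(obs_id, rule.target_id,
                                           _coalesce(segments),
                                           polarities.pop())
                first = min(chosen)
                drop.update(chosen)
                replacement[first] = merged

    result = []
    for i, ann in enumerate(annotations):
        if i in replacement:
            result.append(replacement[i])
        elif i not in drop:
            result.append(ann)
    return result


def remove_normal_findings(
    annotations: Sequence[FindingAnnotation],
) -> list[FindingAnnotation]:
    """Drop normal-polarity findings; the task scores only abnormal ones."""
    return [ann for ann in annotations if ann.polarity is Polarity.ABNORMAL]


def curate(
    observations: Sequence[Observation],
    annotations: Sequence[FindingAnnotation],
    merge_rules: Sequence[MergeRule] = (),
    concept_policy: ResolvePolicy = ResolvePolicy.MAJORITY,
    manual_map: Mapping[str, str] | None = None,
) -> tuple[list[FindingAnnotation], list[InconsistencyReport]]:
    """Full consistency pass: resolve concept inconsistencies, apply merges,
    drop normal findings.  Returns the curated annotations and the (pre-
    resolution) inconsistency reports for review.  Observation texts are
    never altered.  The pass is idempotent."""
    reports = (detect_span_inconsistencies(annotations, observations)
               + detect_concept_inconsistencies(annotations, observations))
    concept_reports = [r for r in reports
                       if r.kind is InconsistencyKind.CONCEPT]
    resolved, _ = resolve_concept_inconsistencies(
        annotations, observations, concept_reports, concept_policy, manual_map)
    merged = apply_merge_rules(resolved, merge_rules)
    return remove_normal_findings(merged), reports


def write_reports_tsv(path: str | Path,
                      reports: Sequence[InconsistencyReport]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["kind", "key", "variant", "count", "example_observation"])
        for report in reports:
            for variant in report.variants:
                writer.writerow([report.kind.value, report.key, variant.value,
                                 variant.count, variant.example_observation_id])


def read_manual_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: case-folded surface form -> HPO ID."""
    mapping = {}
    with open(path, encoding="utf-8", newline="") as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if len(row) >= 2 and row[0].strip():
                mapping[row[0].strip().casefold()] = row[1].strip()
    return mapping
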