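"""End-to-end orchestration: text in, normalized findings and scores out.

Per observation the pipeline pre-processes the text, builds the prompt
(optionally selecting few-shot examples for it), calls the backend, parses
the response table, recovers spans, and normalizes each prediction to an
HPO concept.  Per-observation failures are logged and recorded, never
aborting a run.  A manifest capturing the configuration and seeds is
written next to the outputs so any run can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

from .corpus_io import FindingAnnotation, Observation, Polarity
from .evaluation import (EvalReport, EvalSetting, ScoredPrediction,
                         evaluate_all)
from .fewshot import (ExamplePool, SelectionConfig, TokenEmbedder,
                      TrickyRegistry, select_examples)
from .llm_backend import (Backend, RetryPolicy, TransportError,
                          complete_with_retry)
from .normalizer import (NormalizationMode, NormalizationResult,
                         TermDictionary, normalize_entity)
from .prompting import (DEFAULT_SYSTEM_TEXT, build_inference_prompt,
                        preprocess_text)
from .response_parser import EntityPrediction, parse_entity_table

logger = logging.getLogger(__name__)


class LearningMode(str, Enum):
    FINETUNED = "finetuned"
    FEWSHOT = "fewshot"


@dataclass
class RunConfig:
    mode: LearningMode = LearningMode.FEWSHOT
    normalization_mode: NormalizationMode = NormalizationMode.OBSERVED_AND_PREFERRED
    system_text: str = DEFAULT_SYSTEM_TEXT
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    retry: RetryPolicy = field(default_factory=RetryPolicy)
    count_unnormalized_as_fp: bool = False


@dataclass
class ObservationResult:
    observation: Observation
    predictions: list[EntityPrediction]
    normalizations: list[NormalizationResult]
    failed: bool = False
    error: str = ""

    def scored(self) -> list[ScoredPrediction]:
        out = []
        for pred, norm in zip(self.predictions, self.normalizations):
            out.append(ScoredPrediction(self.observation.id, norm.hpo_id,
                                        pred.spans))
        return out


@dataclass
class RunResult:
    results: list[ObservationResult]
    reports: dict[EvalSetting, EvalReport] | None
    manifest: dict

    def scored_predictions(self) -> list[ScoredPrediction]:
        return [sp for res in self.results for sp in res.scored()]


def run_pipeline(
    cfg: RunConfig,
    observations: Sequence[Observation],
    backend: Backend,
    dictionary: TermDictionary,
    pool: ExamplePool | None = None,
    registry: TrickyRegistry | None = None,
    embedder: TokenEmbedder | None = None,
    gold: Sequence[FindingAnnotation] | None = None,
) -> RunResult:
    """Run extraction + normalization over ``observations``.

    Few-shot mode requires ``pool`` and ``registry``.  When ``gold`` is
    supplied, the run is scored under all three settings against its
    abnormal findings.
    """
    if cfg.mode is LearningMode.FEWSHOT and (pool is None or registry is None):
        raise ValueError("fewshot mode requires an example pool and a "
                         "tricky-example registry")

    results: list[ObservationResult] = []
    for obs in observations:
        query = preprocess_text(obs.text)
        try:
            if cfg.mode is LearningMode.FEWSHOT:
                examples = select_examples(query, pool, registry,
                                           cfg.selection, embedder)
                fewshot_pairs = [(e.user_content, e.assistant_content)
                                 for e in examples]
            else:
                fewshot_pairs = []
            prompt = build_inference_prompt(cfg.system_text, fewshot_pairs,
                                            query)
            response = complete_with_retry(backend, prompt, cfg.retry)
            predictions = parse_entity_table(response.content, query)
            normalizations = [normalize_entity(pred, dictionary,
                                               cfg.normalization_mode)
                              for pred in predictions]
            results.append(ObservationResult(obs, predictions, normalizations))
        except TransportError as exc:
            logger.error("observation %s failed after retries: %s", obs.id, exc)
            results.append(ObservationResult(obs, [], [], failed=True,
                                             error=str(exc)))

    reports = None
    if gold is not None:
        abnormal = [a for a in gold if a.polarity is Polarity.ABNORMAL]
        known = {obs.id for obs in observations}
        reports = evaluate_all(abnormal,
                               [sp for res in results for sp in res.scored()],
                               known_observations=known,
                               count_unnormalized_as_fp=cfg.count_unnormalized_as_fp)

    manifest = {
        "mode": cfg.mode.value,
        "normalization_mode": cfg.normalization_mode.value,
        "selection": dataclasses.asdict(cfg.selection),
        "n_observations": len(observations),
        "n_failed": sum(res.failed for res in results),
        "dictionary_size": len(dictionary),
        "backend": type(backend).__name__,
    }
    return RunResult(results, reports, manifest)


def write_manifest(path: str | Path, run: RunResult) -> None:
    Path(path).write_text(json.dumps(run.manifest, indent=1), encoding="utf-8")


def build_gold_replay_index(
    observations: Sequence[Observation],
    annotations: Sequence[FindingAnnotation],
    preferred_lookup,
) -> dict[str, str]:
    """Map each pre-processed observation text to its gold entity table
    (abnormal findings only), for replay backends."""
    from .prompting import annotations_to_rows, render_entity_table

    by_obs: dict[str, list[FindingAnnotation]] = {o.id: [] for o in observations}
    for ann in annotations:
        if ann.polarity is Polarity.ABNORMAL:
            by_obs[ann.observation_id].append(ann)
    index = {}
    for obs in observations:
        rows = annotations_to_rows(obs, by_obs[obs.id], preferred_lookup)
        index[preprocess_text(obs.text)] = render_entity_table(rows)
    return index
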