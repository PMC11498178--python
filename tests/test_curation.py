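import pytest

from phenonorm.corpus_io import (FindingAnnotation, Observation, Polarity,
                                 SpanSet)
from phenonorm.curation import (InconsistencyKind, MergeRule, ResolvePolicy,
                                apply_merge_rules, curate,
                                detect_concept_inconsistencies,
                                detect_span_inconsistencies,
                                remove_normal_findings,
                                resolve_concept_inconsistencies)


def _ann(obs_id, hpo, segments, polarity=Polarity.ABNORMAL):
    return FindingAnnotation(obs_id, hpo, SpanSet(segments), polarity)


@pytest.fixture()
def modifier_corpus():
    """Two annotations of one concept differing only by a modifier word."""
    observations = [
        Observation("o1", "EYES: Prominent infraorbital creases"),
        Observation("o2", "EYES: Prominent infraorbital creases"),
        Observation("o3", "FACE: long face"),
        Observation("o4", "FACE: elongated face"),
    ]
    annotations = [
        _ann("o1", "HP:0100876", ((16, 36),)),   # "infraorbital creases"
        _ann("o2", "HP:0100876", ((6, 36),)),    # "Prominent infraorbital creases"
        _ann("o3", "HP:0000276", ((6, 15),)),    # "long face"
        _ann("o4", "HP:0000276", ((6, 20),)),    # "elongated face"
    ]
    return observations, annotations


class TestSpanInconsistencies:
    def test_modifier_variants_reported(self, modifier_corpus):
        observations, annotations = modifier_corpus
        reports = detect_span_inconsistencies(annotations, observations)
        assert len(reports) == 1
        report = reports[0]
        assert report.kind is InconsistencyKind.SPAN
        assert report.key == "HP:0100876"
        assert {v.value for v in report.variants} == {
            "infraorbital creases", "Prominent infraorbital creases"}

    def test_content_word_variants_not_reported(self, modifier_corpus):
        # "long face" vs "elongated face" differ by content words, not modifiers
        observations, annotations = modifier_corpus
        reports = detect_span_inconsistencies(annotations, observations)
        assert all(r.key != "HP:0000276" for r in reports)

    def test_consistent_surface_no_report(self):
        observations = [Observation("o1", "FACE: long face")]
        annotations = [_ann("o1", "HP:0000276", ((6, 15),))]
        assert detect_span_inconsistencies(annotations, observations) == []


class TestConceptInconsistencies:
    def test_surface_mapped_to_two_ids(self):
        observations = [
            Observation("n1", "NECK: Excess nuchal skin"),
            Observation("n2", "NECK: excess nuchal skin and"),
        ]
        annotations = [
            _ann("n1", "HP:0005989", ((6, 24),)),
            _ann("n2", "HP:0000474", ((6, 24),)),
        ]
        reports = detect_concept_inconsistencies(annotations, observations)
        assert len(reports) == 1
        assert reports[0].key == "excess nuchal skin"
        assert {v.value for v in reports[0].variants} == {"HP:0005989",
                                                          "HP:0000474"}

    def test_variants_in_descending_count_order(self):
        observations = [Observation(f"o{i}", "NECK: webbed neck")
                        for i in range(8)]
        counts = {"HP:0000465": 5, "HP:0000474": 2, "HP:0005989": 1}
        annotations = []
        i = 0
        for hpo, n in counts.items():
            for _ in range(n):
                annotations.append(_ann(f"o{i}", hpo, ((6, 17),)))
                i += 1
        reports = detect_concept_inconsistencies(annotations, observations)
        assert [v.value for v in reports[0].variants] == \
            ["HP:0000465", "HP:0000474", "HP:0005989"]
        assert [v.count for v in reports[0].variants] == [5, 2, 1]

    def test_consistent_mapping_no_report(self):
        observations = [Observation("o1", "NECK: webbed neck")]
        annotations = [_ann("o1", "HP:0000465", ((6, 17),))]
        assert detect_concept_inconsistencies(annotations, observations) == []


class TestResolve:
    def _corpus(self, id_counts):
        observations, annotations = [], []
        i = 0
        for hpo, n in id_counts.items():
            for _ in range(n):
                observations.append(Observation(f"o{i}", "NECK: webbed neck"))
                annotations.append(_ann(f"o{i}", hpo, ((6, 17),)))
                i += 1
        return observations, annotations

    def test_majority_rewrites_to_most_frequent(self):
        observations, annotations = self._corpus({"HP:0000465": 3,
                                                  "HP:0000474": 1})
        reports = detect_concept_inconsistencies(annotations, observations)
        resolved, flagged = resolve_concept_inconsistencies(
            annotations, observations, reports, ResolvePolicy.MAJORITY)
        assert flagged == []
        assert {a.hpo_id for a in resolved} == {"HP:0000465"}
        # after resolution, detection comes up empty
        assert detect_concept_inconsistencies(resolved, observations) == []

    def test_tie_left_unchanged_and_flagged(self):
        observations, annotations = self._corpus({"HP:0000465": 2,
                                                  "HP:0000474": 2})
        reports = detect_concept_inconsistencies(annotations, observations)
        resolved, flagged = resolve_concept_inconsistencies(
            annotations, observations, reports, ResolvePolicy.MAJORITY)
        assert flagged == ["webbed neck"]
        assert resolved == list(annotations)

    def test_manual_map(self):
        observations, annotations = self._corpus({"HP:0000465": 1,
                                                  "HP:0000474": 1})
        reports = detect_concept_inconsistencies(annotations, observations)
        resolved, flagged = resolve_concept_inconsistencies(
            annotations, observations, reports, ResolvePolicy.MANUAL_MAP,
            manual_map={"webbed neck": "HP:0005989"})
        assert flagged == []
        assert {a.hpo_id for a in resolved} == {"HP:0005989"}


class TestMergeRules:
    rule = MergeRule(("HP:0000369", "HP:0000358"), "HP:0000368")

    def test_co_occurring_sources_merged(self):
        annotations = [
            _ann("o1", "HP:0000369", ((6, 13),)),
            _ann("o1", "HP:0000358", ((20, 26),)),
        ]
        merged = apply_merge_rules(annotations, [self.rule])
        assert len(merged) == 1
        assert merged[0].hpo_id == "HP:0000368"
        assert merged[0].spans.segments == ((6, 13), (20, 26))

    def test_overlapping_segments_coalesced(self):
        annotations = [
            _ann("o1", "HP:0000369", ((6, 15),)),
            _ann("o1", "HP:0000358", ((10, 26),)),
        ]
        merged = apply_merge_rules(annotations, [self.rule])
        assert merged[0].spans.segments == ((6, 26),)

    def test_sources_in_different_observations_untouched(self):
        annotations = [
            _ann("o1", "HP:0000369", ((6, 13),)),
            _ann("o2", "HP:0000358", ((20, 26),)),
        ]
        assert apply_merge_rules(annotations, [self.rule]) == annotations

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            MergeRule(("HP:0000369",), "HP:0000368")
        with pytest.raises(ValueError):
            MergeRule(("HP:0000369", "HP:0000368"), "HP:0000368")


class TestRemoveNormal:
    def test_worked_example(self, exam_annotations):
        kept = remove_normal_findings(exam_annotations)
        assert {a.hpo_id for a in kept} == {"HP:0000664", "HP:0000527",
                                            "HP:0000218"}

    def test_all_abnormal_unchanged(self, exam_annotations):
        abnormal = [a for a in exam_annotations
                    if a.polarity is Polarity.ABNORMAL]
        assert remove_normal_findings(abnormal) == abnormal

    def test_synthetic_count_bookkeeping(self, small_corpus):
        kept = remove_normal_findings(small_corpus.annotations)
        assert len(small_corpus.annotations) - len(kept) == \
            small_corpus.stats.n_normal


class TestFullPass:
    def test_idempotent(self, small_corpus):
        once, _ = curate(small_corpus.observations, small_corpus.annotations)
        twice, _ = curate(small_corpus.observations, once)
        assert twice == once

    def test_texts_never_altered(self, small_corpus):
        texts_before = [o.text for o in small_corpus.observations]
        curate(small_corpus.observations, small_corpus.annotations)
        assert [o.text for o in small_corpus.observations] == texts_before

    def test_resolution_then_detection_empty(self, small_corpus):
        curated, _ = curate(small_corpus.observations, small_corpus.annotations)
        remaining = detect_concept_inconsistencies(curated,
                                                   small_corpus.observations)
        # ties may legitimately remain flagged; everything else resolved
        for report in remaining:
            assert report.variants[0].count == report.variants[1].count
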