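"""Dataset curation: find annotation inconsistencies, merge, drop normals.

Gold annotations drift: the same concept is annotated with and without
modifier words, and one surface form gets mapped to near-duplicate
concepts.  The curation pass detects both, rewrites concepts to the
majority mapping, merges co-occurring concept pairs into their combined
concept, and removes normal-polarity findings (which the task never
scores).
"""

from phenonorm import (FindingAnnotation, MergeRule, Observation, Polarity,
                       SpanSet, curate, detect_concept_inconsistencies,
                       detect_span_inconsistencies)

observations = [
    Observation("o1", "EYES: Prominent infraorbital creases"),
    Observation("o2", "EYES: Prominent infraorbital creases"),
    Observation("n1", "NECK: Excess nuchal skin"),
    Observation("n2", "NECK: excess nuchal skin and"),
    Observation("n3", "NECK: excess nuchal skin seen"),
]
annotations = [
    FindingAnnotation("o1", "HP:0100876", SpanSet(((16, 36),))),  # no modifier
    FindingAnnotation("o2", "HP:0100876", SpanSet(((6, 36),))),   # with it
    FindingAnnotation("n1", "HP:0005989", SpanSet(((6, 24),))),
    FindingAnnotation("n2", "HP:0000474", SpanSet(((6, 24),))),
    FindingAnnotation("n3", "HP:0000474", SpanSet(((6, 24),))),
]

for report in detect_span_inconsistencies(annotations, observations):
    print(f"span inconsistency for {report.key}:")
    for variant in report.variants:
        print(f"  {variant.count}x {variant.value!r}")

for report in detect_concept_inconsistencies(annotations, observations):
    print(f"concept inconsistency for {report.key!r}:")
    for variant in report.variants:
        print(f"  {variant.count}x {variant.value}")

curated, reports = curate(observations, annotations)
print(f"\nafter curation (majority vote): "
      f"{sorted({a.hpo_id for a in curated})}")
# HP:0000474 wins 2:1 for "excess nuchal skin"; the span variants are
# reported for manual review (automatic span repair is deliberately not
# attempted).

rule = MergeRule(("HP:0000369", "HP:0000358"), "HP:0000368")
ears = [
    FindingAnnotation("e1", "HP:0000369", SpanSet(((6, 13),))),   # low-set
    FindingAnnotation("e1", "HP:0000358", SpanSet(((20, 37),))),  # post. rotated
]
merged, _ = curate([Observation("e1", "EARS: low-set, posteriorly rotated")],
                   ears, merge_rules=[rule])
print(f"merge rule: {[(a.hpo_id, a.spans.segments) for a in merged]}")
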