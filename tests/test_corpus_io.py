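import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenonorm.corpus_io import (CorpusDialect, CorpusFormatError, Observation,
                                 Polarity, SpanSet, parse_spans,
                                 read_annotated_corpus, read_term_table,
                                 serialize_spans, write_annotated_corpus,
                                 write_term_obo, write_term_table)
from phenonorm.synthetic import FIXTURE_TERMS

EXAM_TSV = """\
Observation ID\tText\tHPO ID\tSpans\tPolarity
D433F04E6AD5E56\tEYES: partial synophrys, long lashes, horizontal slant\tHP:0000664\t14–23\t–
D433F04E6AD5E56\tEYES: partial synophrys, long lashes, horizontal slant\tHP:0000527\t25–36\t–
8A1EEF66A345576\tMOUTH: normal lips, tongue, high palate\tHP:0000218\t28–39\t–
8A1EEF66A345576\tMOUTH: normal lips, tongue, high palate\tHP:0000159\t7–18\tX
8A1EEF66A345576\tMOUTH: normal lips, tongue, high palate\tHP:0000157\t7–13, 20–26\tX
879246677902DE5\tNEUROLOGIC: very active\tNA\tNA\tNA
"""


class TestSpanCodec:
    @pytest.mark.parametrize("string,segments", [
        ("14–23", ((14, 23),)),
        ("14-23", ((14, 23),)),          # ASCII hyphen accepted on read
        ("7–13, 20–26", ((7, 13), (20, 26))),
        ("", ()),
    ])
    def test_parse(self, string, segments):
        assert parse_spans(string).segments == segments

    @pytest.mark.parametrize("spans,string", [
        (SpanSet(((14, 23),)), "14–23"),
        (SpanSet(((7, 13), (20, 26))), "7–13, 20–26"),
        (SpanSet(()), ""),
    ])
    def test_serialize(self, spans, string):
        assert serialize_spans(spans) == string

    @pytest.mark.parametrize("bad", ["x–3", "9–4", "5–5", "3", "1–2;3–4"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(CorpusFormatError):
            parse_spans(bad)

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 80)),
                    max_size=5))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, raw):
        # build non-overlapping sorted segments from gaps and lengths
        segments, pos = [], 0
        for gap, length in raw:
            start = pos + gap
            segments.append((start, start + length))
            pos = start + length
        spans = SpanSet(tuple(segments))
        assert parse_spans(serialize_spans(spans)) == spans

    def test_invalid_spanset_rejected(self):
        with pytest.raises(ValueError):
            SpanSet(((5, 3),))
        with pytest.raises(ValueError):
            SpanSet(((0, 4), (2, 8)))  # overlapping


class TestObservation:
    def test_organ_header(self):
        assert Observation("a", "EYES: partial synophrys").organ_header == "EYES"
        assert Observation("b", "note without colon").organ_header == ""
        assert Observation("c", "Mouth: x").organ_header == "MOUTH"

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            Observation("a", "")


class TestReadCorpus:
    def test_worked_example(self):
        observations, annotations = read_annotated_corpus(io.StringIO(EXAM_TSV))
        assert len(observations) == 3
        assert len(annotations) == 5
        eyes = annotations[0]
        assert eyes.hpo_id == "HP:0000664"
        assert eyes.spans.segments == ((14, 23),)
        # the printed offsets select the surface form
        text = observations[0].text
        assert text[14:23] == "synophrys"
        disjoint = annotations[4]
        assert disjoint.spans.segments == ((7, 13), (20, 26))
        assert disjoint.polarity is Polarity.NORMAL

    def test_empty_observation_has_no_annotations(self):
        observations, annotations = read_annotated_corpus(io.StringIO(EXAM_TSV))
        neuro = [o for o in observations if o.id == "879246677902DE5"]
        assert len(neuro) == 1
        assert not any(a.observation_id == "879246677902DE5"
                       for a in annotations)

    def test_duplicate_rows_deduplicated_with_warning(self):
        doubled = EXAM_TSV + EXAM_TSV.splitlines(keepends=True)[1]
        with pytest.warns(UserWarning, match="duplicate"):
            _, annotations = read_annotated_corpus(io.StringIO(doubled))
        assert len(annotations) == 5

    def test_malformed_span_names_row(self):
        bad = EXAM_TSV.replace("14–23", "23–14", 1)
        with pytest.raises(CorpusFormatError, match="row 2"):
            read_annotated_corpus(io.StringIO(bad))

    def test_missing_column_rejected(self):
        with pytest.raises(CorpusFormatError, match="Spans"):
            read_annotated_corpus(io.StringIO("Observation ID\tText\tHPO ID\n"))

    def test_custom_dialect(self):
        dialect = CorpusDialect(id_col="oid", text_col="txt", hpo_col="concept",
                                spans_col="where", polarity_col="pol")
        content = ("oid\ttxt\tconcept\twhere\tpol\n"
                   "x1\tEYES: synophrys\tHP:0000664\t6-15\t–\n")
        observations, annotations = read_annotated_corpus(io.StringIO(content),
                                                          dialect)
        assert annotations[0].spans.segments == ((6, 15),)

    def test_write_read_round_trip(self, tmp_path, small_corpus):
        path = tmp_path / "corpus.tsv"
        write_annotated_corpus(path, small_corpus.observations,
                               small_corpus.annotations)
        observations, annotations = read_annotated_corpus(path)
        assert observations == small_corpus.observations
        assert annotations == small_corpus.annotations

    def test_reading_is_deterministic(self, tmp_path, small_corpus):
        path = tmp_path / "corpus.tsv"
        write_annotated_corpus(path, small_corpus.observations,
                               small_corpus.annotations)
        assert read_annotated_corpus(path) == read_annotated_corpus(path)

    def test_all_parsed_spans_within_text(self, small_corpus, tmp_path):
        path = tmp_path / "corpus.tsv"
        write_annotated_corpus(path, small_corpus.observations,
                               small_corpus.annotations)
        observations, annotations = read_annotated_corpus(path)
        texts = {o.id: o.text for o in observations}
        assert all(a.spans.valid_for(texts[a.observation_id])
                   for a in annotations)


class TestTermTable:
    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "terms.tsv"
        write_term_table(path, FIXTURE_TERMS)
        terms = read_term_table(path, "tsv")
        assert terms == list(FIXTURE_TERMS)
        by_id = {t.hpo_id: t for t in terms}
        assert "excess nuchal skin" in by_id["HP:0000474"].synonyms
        assert by_id["HP:0005989"].preferred_term == "redundant neck skin"

    def test_obo_minimal(self, tmp_path):
        path = tmp_path / "terms.obo"
        write_term_obo(path, FIXTURE_TERMS)
        terms = read_term_table(path, "obo-minimal")
        assert {t.hpo_id for t in terms} == {t.hpo_id for t in FIXTURE_TERMS}
        by_id = {t.hpo_id: t for t in terms}
        # OBO quoting and scope qualifiers stripped from synonyms
        assert by_id["HP:0005989"].synonyms == ("excess neck skin",)

    def test_empty_tsv(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("hpo_id\tpreferred_term\tsynonyms\n")
        assert read_term_table(path, "tsv") == []

    def test_row_without_name_skipped(self, tmp_path):
        path = tmp_path / "terms.tsv"
        path.write_text("hpo_id\tpreferred_term\nHP:0000001\t\nHP:0000002\tok\n")
        with pytest.warns(UserWarning, match="skipped"):
            terms = read_term_table(path, "tsv")
        assert [t.hpo_id for t in terms] == ["HP:0000002"]
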