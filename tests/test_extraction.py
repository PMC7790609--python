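"""Sentence segmentation, anchor detection, and rule-based mention extraction."""

import re

import pytest

from dvminer import (
    POI,
    VICTIM,
    EventRecord,
    GeneratorConfig,
    extract_mentions,
    find_anchors,
    generate,
    segment_sentences,
)


def _event(narrative, **kw):
    return EventRecord(event_id="T0001", narrative=narrative, **kw)


class TestSegmentSentences:
    def test_two_terminated_sentences(self):
        spans = segment_sentences("POI has depression. Victim was unharmed.")
        assert len(spans) == 2

    def test_empty_narrative(self):
        assert segment_sentences("") == []

    def test_generated_narrative_matches_terminator_oracle(self, lexicon, rules):
        # oracle: count of terminator-delimited non-empty segments
        events, _ = generate(GeneratorConfig(n_events=5, seed=13), lexicon, rules)
        for event in events:
            oracle = len(
                [s for s in re.split(r"(?<=[.!?])\s+", event.narrative) if s.strip()]
            )
            assert len(segment_sentences(event.narrative)) == oracle

    def test_intervals_disjoint_ordered_and_cover_text(self):
        text = "First sentence.  Second one!   Third?"
        spans = segment_sentences(text)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        covered = set()
        for s, e in spans:
            covered.update(range(s, e))
        for i, ch in enumerate(text):
            if not ch.isspace():
                assert i in covered


class TestFindAnchors:
    def test_defendant_is_poi_anchor(self, rules):
        hits = find_anchors("the defendant has mental health issues", rules)
        assert [(role, span) for role, span in hits] == [(POI, (4, 13))]

    def test_victim_anchor(self, rules):
        hits = find_anchors("victim is suffering from a severe mental disorder", rules)
        assert hits[0][0] == VICTIM
        assert hits[0][1] == (0, 6)

    def test_no_anchor_in_neutral_text(self, rules):
        assert find_anchors("the weather was bad", rules) == []

    def test_word_boundary_prevents_substring_hits(self, rules):
        # "vic" must not fire inside "service" or "victoria"
        assert find_anchors("the service in victoria was convicted", rules) == []


class TestExtractMentions:
    def test_poi_suffering_from_dementia(self, lexicon, rules):
        mentions = extract_mentions(_event("POI is suffering from dementia."), lexicon, rules)
        assert len(mentions) == 1
        m = mentions[0]
        assert m.subject == POI
        assert m.node_code == "F03"
        assert m.surface == "dementia"

    def test_victim_diagnosed_with_paranoid_schizophrenia(self, lexicon, rules):
        mentions = extract_mentions(
            _event("The victim was diagnosed with paranoid schizophrenia."), lexicon, rules
        )
        assert len(mentions) == 1
        assert mentions[0].subject == VICTIM
        assert mentions[0].node_code == "F20.0"

    def test_accused_takes_antidepressants(self, lexicon, rules):
        mentions = extract_mentions(
            _event("Accused takes a number of antidepressants."), lexicon, rules
        )
        assert len(mentions) == 1
        assert mentions[0].subject == POI
        assert mentions[0].node_code == "MED-ANTIDEPRESSANT"

    def test_duplicate_condition_collapses_to_one(self, lexicon, rules):
        narrative = "POI has depression. The POI mentioned his depression again."
        mentions = extract_mentions(_event(narrative), lexicon, rules)
        assert len(mentions) == 1
        # first occurrence kept
        assert mentions[0].span[0] == narrative.index("depression")

    def test_two_distinct_conditions_both_kept(self, lexicon, rules):
        mentions = extract_mentions(
            _event("POI has depression. POI also has schizophrenia."), lexicon, rules
        )
        assert {m.node_code for m in mentions} == {"F32", "F20.9"}

    def test_anchor_free_sentence_produces_nothing(self, lexicon, rules):
        mentions = extract_mentions(
            _event("A pamphlet about depression was on the table."), lexicon, rules
        )
        assert mentions == []

    def test_no_cross_sentence_attribution(self, lexicon, rules):
        # anchor in sentence 1, illness term in anchor-free sentence 2
        mentions = extract_mentions(
            _event("The POI was agitated. A flyer about depression lay nearby."),
            lexicon,
            rules,
        )
        assert mentions == []

    def test_longest_match_wins_over_contained_term(self, lexicon, rules):
        mentions = extract_mentions(
            _event("Victim has paranoid schizophrenia."), lexicon, rules
        )
        assert [m.node_code for m in mentions] == ["F20.0"]

    def test_nearest_anchor_attribution(self, lexicon, rules):
        # "victim" is strictly nearer to the hit than "POI"
        mentions = extract_mentions(
            _event("The POI said that the victim has depression."), lexicon, rules
        )
        assert mentions[0].subject == VICTIM

    def test_anchor_distance_tie_prefers_preceding(self, lexicon, rules):
        narrative = "POI aaa depression aaa vic."
        start = narrative.index("depression")
        end = start + len("depression")
        assert start - len("POI") == narrative.index("vic") - end  # exact tie
        mentions = extract_mentions(_event(narrative), lexicon, rules)
        assert mentions[0].subject == POI

    def test_span_indexes_raw_narrative(self, lexicon, rules):
        narrative = "The Victim Takes VALIUM."
        mentions = extract_mentions(_event(narrative), lexicon, rules)
        (m,) = mentions
        s, e = m.span
        assert narrative[s:e].lower() == m.surface.lower() == "valium"

    def test_negation_is_not_handled(self, lexicon, rules):
        # documented limitation: extraction is precision-oriented, not clausal
        mentions = extract_mentions(
            _event("POI does not have depression."), lexicon, rules
        )
        assert len(mentions) == 1

    def test_determinism(self, lexicon, rules):
        event = _event(
            "POI has bipolar disorder and takes zoloft. The victim suffers from anxiety."
        )
        first = extract_mentions(event, lexicon, rules)
        for _ in range(3):
            assert extract_mentions(event, lexicon, rules) == first


class TestEventRecordValidation:
    def test_age_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="age"):
            EventRecord(event_id="X", narrative="", poi_age=130)

    def test_negative_person_count_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            EventRecord(event_id="X", narrative="", n_pois=-1)

    def test_round_trips_through_dict(self):
        e = EventRecord(event_id="X", narrative="text.", poi_id="P1", victim_id="V1",
                        poi_age=30, victim_age=40, mi_flag=True, year=2010)
        assert EventRecord.from_dict(e.to_dict()) == e
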