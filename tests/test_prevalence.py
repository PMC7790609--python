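"""Percentages, confidence intervals, event partition, category tables and
the fixed-field comparison."""

import pytest

from dvminer import (
    EventRecord,
    GeneratorConfig,
    Mention,
    POI,
    VICTIM,
    category_table,
    event_prevalence,
    extract_corpus,
    filter_single,
    fixed_field_comparison,
    generate,
    normalize_all,
    percent,
    proportion_ci95,
    stratified_table,
)


def _event(eid, mi_flag=False, **kw):
    return EventRecord(event_id=eid, narrative="", mi_flag=mi_flag,
                       poi_id=f"P-{eid}", victim_id=f"V-{eid}", **kw)


def _mention(eid, subject=POI, node_code="F32"):
    return Mention(event_id=eid, subject=subject, surface="s", node_code=node_code,
                   span=(0, 1), anchor="a", pattern_id="p")


class TestPercent:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(64587, 416441, 15.51), (49154, 64587, 76.11), (0, 100, 0.00),
         (4295, 416441, 1.03), (1, 3, 33.33), (1, 8, 12.50)],
    )
    def test_half_up_two_decimals(self, num, den, expected):
        assert percent(num, den) == expected

    def test_exact_half_rounds_up(self):
        # 0.125% would round to 0.12 under banker's rounding
        assert percent(1, 800) == 0.13

    def test_zero_denominator_is_domain_error(self):
        with pytest.raises(ValueError):
            percent(1, 0)

    def test_numerator_above_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent(5, 4)


class TestProportionCI:
    @pytest.mark.parametrize(
        "num,den,low,high",
        [(11523, 311210, 3.6, 3.8), (3718, 96228, 3.7, 4.0),
         (12048, 74323, 15.9, 16.5), (40514, 329306, 12.2, 12.4)],
    )
    def test_normal_approximation_reproduces_printed_bounds(self, num, den, low, high):
        assert proportion_ci95(num, den) == (low, high)

    def test_p_zero_collapses_interval(self):
        assert proportion_ci95(0, 100) == (0.0, 0.0)

    def test_bounds_clipped_to_unit_interval(self):
        low, high = proportion_ci95(1, 4)
        assert 0.0 <= low <= high <= 100.0

    def test_wilson_interval_available_and_contains_p(self):
        low, high = proportion_ci95(30, 100, method="wilson")
        assert low < 30.0 < high

    def test_zero_denominator_is_domain_error(self):
        with pytest.raises(ValueError):
            proportion_ci95(1, 0)


class TestEventPrevalence:
    def test_no_mentions(self):
        events = [_event(f"e{i}") for i in range(10)]
        ep = event_prevalence(events, [])
        assert (ep.n_none, ep.n_poi_only, ep.n_victim_only, ep.n_both) == (10, 0, 0, 0)

    def test_both_roles_counted_once_in_both(self):
        events = [_event("e1")]
        ep = event_prevalence(events, [_mention("e1", POI), _mention("e1", VICTIM)])
        assert (ep.n_poi_only, ep.n_victim_only, ep.n_both) == (0, 0, 1)

    def test_partition_sums_to_corpus_size(self, lexicon, rules):
        events, _ = generate(GeneratorConfig(n_events=1200, seed=21), lexicon, rules)
        filtered = filter_single(events)
        ids = {e.event_id for e in filtered}
        mentions = [m for m in extract_corpus(events, lexicon, rules) if m.event_id in ids]
        ep = event_prevalence(filtered, mentions)
        assert ep.n_none + ep.n_poi_only + ep.n_victim_only + ep.n_both == len(filtered)

    def test_partition_matches_generator_gold(self, lexicon, rules):
        config = GeneratorConfig(n_events=1200, seed=23, typo_rate=0.0, distractor_rate=0.0)
        events, gold = generate(config, lexicon, rules)
        filtered = filter_single(events)
        ids = {e.event_id for e in filtered}
        mentions = [m for m in extract_corpus(events, lexicon, rules) if m.event_id in ids]
        ep = event_prevalence(filtered, mentions)
        gold_poi = {e.event_id for e in gold.events
                    if e.event_id in ids and any(m.role == POI for m in e.mentions)}
        gold_vic = {e.event_id for e in gold.events
                    if e.event_id in ids and any(m.role == VICTIM for m in e.mentions)}
        assert ep.n_both == len(gold_poi & gold_vic)
        assert ep.n_poi_only == len(gold_poi - gold_vic)
        assert ep.n_victim_only == len(gold_vic - gold_poi)


class TestCategoryTable:
    def test_pct_and_prevalence_columns(self, hierarchy):
        # 2 POI mentions of F32, 1 of F99, 1 victim mention of F32; 50 events
        mentions = [_mention("e1", POI, "F32"), _mention("e2", POI, "F32"),
                    _mention("e3", POI, "F99"), _mention("e4", VICTIM, "F32")]
        leveled = normalize_all(mentions, hierarchy)
        table = category_table(leveled, 50, hierarchy, level=1)
        row = table.set_index("code").loc["F30-39"]
        assert row["count_poi"] == 2
        assert row["pct_poi"] == pytest.approx(66.67)
        assert row["prev_poi"] == pytest.approx(4.00)
        assert row["count_victim"] == 1
        assert row["pct_victim"] == pytest.approx(100.00)

    def test_single_category_is_100_percent(self, hierarchy):
        leveled = normalize_all([_mention("e1", POI, "F32")], hierarchy)
        table = category_table(leveled, 10, hierarchy, level=1)
        assert table.loc[0, "pct_poi"] == 100.00

    def test_rows_sorted_by_poi_count_descending(self, hierarchy, lexicon, rules):
        events, _ = generate(GeneratorConfig(n_events=1000, seed=31), lexicon, rules)
        leveled = normalize_all(extract_corpus(events, lexicon, rules), hierarchy)
        table = category_table(leveled, len(events), hierarchy, level=1)
        counts = table["count_poi"].tolist()
        assert counts == sorted(counts, reverse=True)

    def test_level2_table_drops_level1_only_mentions(self, hierarchy):
        leveled = normalize_all(
            [_mention("e1", POI, "F99"), _mention("e2", POI, "F32")], hierarchy
        )
        table = category_table(leveled, 10, hierarchy, level=2)
        assert table["code"].tolist() == ["F32"]


class TestFixedFieldComparison:
    def test_flag_percentage(self):
        events = [_event(f"e{i}", mi_flag=(i < 2)) for i in range(100)]
        ff = fixed_field_comparison(events, [_mention("e5")])
        assert ff.flag_count == 2
        assert ff.flag_pct == 2.00
        assert ff.mined_count == 1

    def test_all_flagged_and_mined_gives_ratio_one(self):
        events = [_event(f"e{i}", mi_flag=True) for i in range(4)]
        mentions = [_mention(f"e{i}") for i in range(4)]
        assert fixed_field_comparison(events, mentions).ratio == 1.00

    def test_zero_flags_reports_undefined_marker(self):
        events = [_event("e1")]
        assert fixed_field_comparison(events, [_mention("e1")]).ratio is None


class TestStratifiedTable:
    def test_unknown_sex_excluded_from_strata(self):
        events = [
            _event("e1", poi_sex="female"),
            _event("e2", poi_sex="male"),
            _event("e3", poi_sex="unknown"),
        ]
        table = stratified_table(events, [_mention("e1")], by="sex")
        poi_rows = table[table["role"] == POI]
        assert poi_rows["denominator"].sum() == 2  # e3 excluded

    def test_age_strata_use_seven_bands(self, lexicon, rules):
        events, _ = generate(GeneratorConfig(n_events=1500, seed=33), lexicon, rules)
        filtered = filter_single(events)
        mentions = extract_corpus(filtered, lexicon, rules)
        table = stratified_table(filtered, mentions, by="age")
        assert set(table["stratum"]) <= {"0-14", "15-24", "25-34", "35-44",
                                         "45-54", "55-64", "65+"}
        # CI bounds bracket the point estimate
        for row in table.itertuples(index=False):
            assert row.ci_low <= row.percent <= row.ci_high
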