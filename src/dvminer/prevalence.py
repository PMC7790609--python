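"""Prevalence statistics: event-level and person-level proportions, category
tables, sex/age stratifications, fixed-field comparison, and 95% CIs.

Percentages are half-up rounded to 2 decimals and confidence bounds to
1 decimal — matching how such tables are conventionally printed.  Confidence
intervals default to the binomial normal approximation
``p ± 1.96·sqrt(p(1−p)/n)``; Wilson score intervals are available behind a
``method`` switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal, getcontext
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cohort import AGE_BANDS, age_band
from .extraction import POI, VICTIM, EventRecord, Mention
from .icd_mapper import LeveledMention
from .lexicon import Hierarchy

__all__ = [
    "percent",
    "proportion_ci95",
    "EventPrevalence",
    "event_prevalence",
    "category_table",
    "FixedFieldComparison",
    "fixed_field_comparison",
    "stratified_table",
    "unique_person_prevalence",
    "PrevalenceReport",
    "build_report",
]

getcontext().prec = 40

_Z95 = 1.96


def _round_half_up(value: float | Decimal, ndigits: int) -> float:
    if not isinstance(value, Decimal):
        value = Decimal(repr(value))
    q = Decimal(1).scaleb(-ndigits)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def percent(num: int, den: int) -> float:
    """``100·num/den`` half-up rounded to 2 decimals.

    >>> percent(64587, 416441)
    15.51
    """
    if den == 0:
        raise ValueError("denominator must be positive")
    if not 0 <= num <= den:
        raise ValueError(f"numerator {num} outside 0..{den}")
    return _round_half_up(Decimal(num) * 100 / Decimal(den), 2)


def proportion_ci95(num: int, den: int, method: str = "normal") -> tuple[float, float]:
    """95% confidence interval for a binomial proportion, as percentages
    half-up rounded to 1 decimal and clipped to [0, 100].

    ``method="normal"`` (default) is the normal approximation; ``"wilson"``
    gives the Wilson score interval.
    """
    if den == 0:
        raise ValueError("denominator must be positive")
    p = num / den
    if method == "normal":
        half = _Z95 * math.sqrt(p * (1 - p) / den)
        low, high = p - half, p + half
    elif method == "wilson":
        z2 = _Z95**2
        centre = (p + z2 / (2 * den)) / (1 + z2 / den)
        half = (_Z95 / (1 + z2 / den)) * math.sqrt(p * (1 - p) / den + z2 / (4 * den**2))
        low, high = centre - half, centre + half
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    low = min(max(low * 100, 0.0), 100.0)
    high = min(max(high * 100, 0.0), 100.0)
    return _round_half_up(low, 1), _round_half_up(high, 1)


@dataclass(frozen=True)
class EventPrevalence:
    """Partition of a filtered corpus by which role(s) have mentions."""

    n_total: int
    n_none: int
    n_poi_only: int
    n_victim_only: int
    n_both: int

    @property
    def n_any(self) -> int:
        return self.n_poi_only + self.n_victim_only + self.n_both

    @property
    def pct_any(self) -> float:
        return percent(self.n_any, self.n_total)


def event_prevalence(
    events: Sequence[EventRecord], mentions: Iterable[Mention]
) -> EventPrevalence:
    """Partition events into {no mention, POI-only, victim-only, both}.

    The four counts always sum to the corpus size.
    """
    poi_events: set[str] = set()
    victim_events: set[str] = set()
    for m in mentions:
        (poi_events if m.subject == POI else victim_events).add(m.event_id)
    n_both = n_poi = n_vic = 0
    for e in events:
        p, v = e.event_id in poi_events, e.event_id in victim_events
        if p and v:
            n_both += 1
        elif p:
            n_poi += 1
        elif v:
            n_vic += 1
    n_total = len(events)
    return EventPrevalence(
        n_total=n_total,
        n_none=n_total - n_poi - n_vic - n_both,
        n_poi_only=n_poi,
        n_victim_only=n_vic,
        n_both=n_both,
    )


def category_table(
    leveled_mentions: Iterable[LeveledMention],
    n_events_total: int,
    hierarchy: Hierarchy,
    level: int = 1,
) -> pd.DataFrame:
    """Per-category mention counts by role at a hierarchy level (1, 2 or 3).

    For each code and role: the mention count, the percentage of that role's
    mention total *at this level*, and the prevalence — the count as a
    percentage of all events in the corpus.  Rows are sorted by POI count
    descending (ties broken by code).
    """
    if level not in (1, 2, 3):
        raise ValueError("level must be 1, 2 or 3")
    attr = f"level{level}_code"
    counts: dict[str, dict[str, int]] = {}
    totals = {POI: 0, VICTIM: 0}
    for m in leveled_mentions:
        code = getattr(m, attr)
        if code is None:
            continue
        counts.setdefault(code, {POI: 0, VICTIM: 0})[m.subject] += 1
        totals[m.subject] += 1
    rows = []
    for code, by_role in counts.items():
        rows.append(
            {
                "code": code,
                "label": hierarchy[code].label if code in hierarchy else code,
                "count_poi": by_role[POI],
                "pct_poi": percent(by_role[POI], totals[POI]) if totals[POI] else None,
                "prev_poi": percent(by_role[POI], n_events_total) if n_events_total else None,
                "count_victim": by_role[VICTIM],
                "pct_victim": percent(by_role[VICTIM], totals[VICTIM]) if totals[VICTIM] else None,
                "prev_victim": percent(by_role[VICTIM], n_events_total) if n_events_total else None,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "code", "label", "count_poi", "pct_poi", "prev_poi",
            "count_victim", "pct_victim", "prev_victim",
        ],
    )
    return df.sort_values(["count_poi", "code"], ascending=[False, True], kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class FixedFieldComparison:
    """Structured "mental illness related" flag versus text-mined mentions."""

    n_total: int
    flag_count: int
    flag_pct: float
    mined_count: int
    mined_pct: float
    ratio: Optional[float]  # mined/flag, 2 decimals; None when no event is flagged


def fixed_field_comparison(
    events: Sequence[EventRecord], mentions: Iterable[Mention]
) -> FixedFieldComparison:
    """Contrast the structured flag with mined mentions (sets may overlap)."""
    mention_events = {m.event_id for m in mentions}
    flag_count = sum(1 for e in events if e.mi_flag)
    mined_count = sum(1 for e in events if e.event_id in mention_events)
    n_total = len(events)
    return FixedFieldComparison(
        n_total=n_total,
        flag_count=flag_count,
        flag_pct=percent(flag_count, n_total) if n_total else 0.0,
        mined_count=mined_count,
        mined_pct=percent(mined_count, n_total) if n_total else 0.0,
        ratio=_round_half_up(mined_count / flag_count, 2) if flag_count else None,
    )


def stratified_table(
    events: Sequence[EventRecord],
    mentions: Iterable[Mention],
    by: str,
    ci_method: str = "normal",
) -> pd.DataFrame:
    """Role-specific mention proportions stratified by sex or age band.

    ``by`` is ``"sex"`` or ``"age"``.  Events with unknown sex/age for a role
    are excluded from that role's strata (their absence is why stratum
    denominators need not sum to the corpus size) but remain in all overall
    counts elsewhere.  Each row carries a normal-approximation 95% CI.
    """
    if by not in ("sex", "age"):
        raise ValueError("by must be 'sex' or 'age'")
    mentions = list(mentions)
    rows = []
    for role, sex_attr, age_attr in ((POI, "poi_sex", "poi_age"), (VICTIM, "victim_sex", "victim_age")):
        mention_events = {m.event_id for m in mentions if m.subject == role}
        strata: dict[str, list[int]] = {}
        for e in events:
            if by == "sex":
                key = getattr(e, sex_attr)
                if key not in ("female", "male"):
                    continue
            else:
                age = getattr(e, age_attr)
                if age is None:
                    continue
                key = age_band(age)
            num_den = strata.setdefault(key, [0, 0])
            num_den[1] += 1
            if e.event_id in mention_events:
                num_den[0] += 1
        order = AGE_BANDS if by == "age" else ("female", "male")
        for key in order:
            if key not in strata:
                continue
            num, den = strata[key]
            low, high = proportion_ci95(num, den, method=ci_method)
            rows.append(
                {
                    "role": role,
                    "stratum": key,
                    "numerator": num,
                    "denominator": den,
                    "percent": percent(num, den),
                    "ci_low": low,
                    "ci_high": high,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["role", "stratum", "numerator", "denominator", "percent", "ci_low", "ci_high"],
    )


def unique_person_prevalence(ledger: pd.DataFrame) -> tuple[int, int, float]:
    """``(n_with_mi, n_persons, percent)`` over a person ledger."""
    n_persons = len(ledger)
    n_mi = int(ledger["has_mi"].sum()) if n_persons else 0
    return n_mi, n_persons, percent(n_mi, n_persons) if n_persons else 0.0


@dataclass
class PrevalenceReport:
    """Bundle of every quantitative surface the analysis produces."""

    events_partition: EventPrevalence
    level_counts: dict[str, tuple[int, int, int]]
    category_tables: dict[int, pd.DataFrame]
    by_sex: pd.DataFrame
    by_age: pd.DataFrame
    fixed_field: FixedFieldComparison
    unique_poi: tuple[int, int, float]
    unique_victim: tuple[int, int, float]
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        ep, ff = self.events_partition, self.fixed_field
        return {
            "n_events": ep.n_total,
            "n_events_with_mention": ep.n_any,
            "pct_events_with_mention": ep.pct_any,
            "n_poi_only": ep.n_poi_only,
            "n_victim_only": ep.n_victim_only,
            "n_both": ep.n_both,
            "level_counts": {k: list(v) for k, v in self.level_counts.items()},
            "fixed_field": {
                "flag_count": ff.flag_count,
                "flag_pct": ff.flag_pct,
                "mined_count": ff.mined_count,
                "mined_pct": ff.mined_pct,
                "ratio": ff.ratio,
            },
            "unique_poi": {
                "with_mi": self.unique_poi[0],
                "persons": self.unique_poi[1],
                "pct": self.unique_poi[2],
            },
            "unique_victim": {
                "with_mi": self.unique_victim[0],
                "persons": self.unique_victim[1],
                "pct": self.unique_victim[2],
            },
        }


def build_report(
    events: Sequence[EventRecord],
    mentions: Sequence[Mention],
    leveled: Sequence[LeveledMention],
    poi_ledger: pd.DataFrame,
    victim_ledger: pd.DataFrame,
    hierarchy: Hierarchy,
    ci_method: str = "normal",
) -> PrevalenceReport:
    """Assemble the full report from a filtered corpus and its mentions."""
    from .icd_mapper import level_counts as _level_counts

    return PrevalenceReport(
        events_partition=event_prevalence(events, mentions),
        level_counts={
            "all": _level_counts(leveled),
            "poi": _level_counts(leveled, POI),
            "victim": _level_counts(leveled, VICTIM),
        },
        category_tables={
            lvl: category_table(leveled, len(events), hierarchy, level=lvl) for lvl in (1, 2, 3)
        },
        by_sex=stratified_table(events, mentions, by="sex", ci_method=ci_method),
        by_age=stratified_table(events, mentions, by="age", ci_method=ci_method),
        fixed_field=fixed_field_comparison(events, mentions),
        unique_poi=unique_person_prevalence(poi_ledger),
        unique_victim=unique_person_prevalence(victim_ledger),
    )
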