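"""Cohort restriction and person-level collapsing.

The rule engine cannot associate a mention with a specific individual when an
event involves several POIs or several victims, so the analysis cohort keeps
only events with exactly one of each.  Because the same person can appear in
many events over the study window, event-level proportions and unique-person
prevalence are reported separately; a person's ledger row carries their first
filtered event's sex and age band when values conflict across events.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import pandas as pd

from .extraction import POI, VICTIM, EventRecord, Mention

__all__ = ["AGE_BANDS", "age_band", "filter_single", "build_person_ledgers"]

logger = logging.getLogger(__name__)

#: the seven age bands used for stratified reporting
AGE_BANDS = ("0-14", "15-24", "25-34", "35-44", "45-54", "55-64", "65+")

_BAND_LOWER = (0, 15, 25, 35, 45, 55, 65)


def age_band(age: int) -> str:
    """Map an age in years to one of the seven reporting bands.

    Bands are left-closed at 0, 15, 25, 35, 45, 55 and 65 years; ages 65 and
    over all fall in ``"65+"``.
    """
    if age < 0:
        raise ValueError(f"age must be nonnegative, got {age}")
    for lower, band in zip(reversed(_BAND_LOWER), reversed(AGE_BANDS)):
        if age >= lower:
            return band
    raise AssertionError("unreachable")


def filter_single(events: Iterable[EventRecord]) -> list[EventRecord]:
    """Keep only events with exactly one POI and one victim, preserving order."""
    return [e for e in events if e.n_pois == 1 and e.n_victims == 1]


def _role_mention_events(mentions: Iterable[Mention], role: str) -> set[str]:
    return {m.event_id for m in mentions if m.subject == role}


def build_person_ledgers(
    events: Sequence[EventRecord], mentions: Iterable[Mention]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One ledger row per distinct person per role over a filtered corpus.

    ``has_mi`` is true iff at least one mention with the matching role was
    attributed in any of that person's events.  Returns ``(poi_ledger,
    victim_ledger)`` DataFrames with columns person_id, role, n_events,
    has_mi, sex, age_band.
    """
    mentions = list(mentions)
    ledgers = []
    for role, id_attr, sex_attr, age_attr in (
        (POI, "poi_id", "poi_sex", "poi_age"),
        (VICTIM, "victim_id", "victim_sex", "victim_age"),
    ):
        mention_events = _role_mention_events(mentions, role)
        rows: dict[str, dict] = {}
        for event in events:
            person_id = getattr(event, id_attr)
            if person_id is None:
                raise ValueError(
                    f"{event.event_id}: missing {id_attr} on a single-{role.lower()} event"
                )
            sex = getattr(event, sex_attr)
            age = getattr(event, age_attr)
            row = rows.get(person_id)
            if row is None:
                rows[person_id] = {
                    "person_id": person_id,
                    "role": role,
                    "n_events": 1,
                    "has_mi": event.event_id in mention_events,
                    "sex": sex,
                    "age_band": age_band(age) if age is not None else None,
                }
            else:
                row["n_events"] += 1
                row["has_mi"] = row["has_mi"] or event.event_id in mention_events
                if sex != row["sex"] or (
                    age is not None and row["age_band"] is None
                ):
                    logger.warning(
                        "person %s (%s): conflicting demographics across events; "
                        "keeping first-event values",
                        person_id,
                        role,
                    )
        ledgers.append(
            pd.DataFrame(
                list(rows.values()),
                columns=["person_id", "role", "n_events", "has_mi", "sex", "age_band"],
            )
        )
    return ledgers[0], ledgers[1]
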