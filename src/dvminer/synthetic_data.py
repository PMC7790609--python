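"""Synthetic police DV event corpora with gold annotations.

The real corpus behind this kind of analysis (police-recorded domestic
violence events combining fixed fields and free-text narratives) is
confidential, so this module generates structurally faithful stand-ins: short
template-based narratives in which role anchors ("POI", "defendant",
"victim", ...) license illness and medication mentions, with configurable
per-role mention probabilities, a category mix defaulting to the relative
frequencies observed in large police corpora, misspelling perturbation drawn
from the lexicon's explicit variants, anchor-free distractor sentences, and
multi-POI/multi-victim events to exercise the cohort filter.

Default rates are calibrated to corpus-scale figures: ~84.6% of events are
single-POI/single-victim, ~12.8% of events carry a POI mention, ~3.7% a
victim mention, and ~1% are flagged "mental illness related" in the fixed
fields.  Every planted surface form (including typo perturbations) exists in
the shipped lexicon, so recall on typo-free templates is 1 by construction;
distractor sentences are never in gold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional
import random

from pydantic import BaseModel, Field, field_validator

from .extraction import POI, VICTIM, EventRecord, RuleSet, default_rules
from .lexicon import Lexicon, default_lexicon

__all__ = [
    "GeneratorConfig",
    "GoldMention",
    "GoldEvent",
    "GoldPerson",
    "GoldLedger",
    "generate",
    "corpus_summary",
]

# --------------------------------------------------------------------------
# default parameter tables
# --------------------------------------------------------------------------

#: per-role level-1 category weights (proportional to mention counts reported
#: for large police DV corpora; unnormalized)
DEFAULT_CATEGORY_WEIGHTS: dict[str, dict[str, float]] = {
    POI: {
        "F99": 22172, "F30-39": 12753, "F90-99": 7735, "F10-19": 5642,
        "F20-29": 4751, "F40-49": 3034, "X71-83": 2702, "X-SUBSTANCE-ABUSE": 2310,
        "F80-89": 1492, "F70-79": 1276, "F60-69": 1096, "T08-T14": 687,
        "X-TBI": 568, "F01-09": 498, "MED-ANTIDEPRESSANT": 326, "R40-46": 168,
        "MED-ANTIPSYCHOTIC": 108, "MED-ANTIANXIETY": 77, "G30-32": 54,
        "Q90-99": 48, "X-DRUG-INDUCED": 43, "F50-59": 24, "G10-14": 11,
        "G00-99": 3, "X-DRUG-RX-ABUSE": 3, "MED-NEUROLEPTIC": 1,
    },
    VICTIM: {
        "F99": 4208, "F30-39": 4288, "F90-99": 1787, "F10-19": 1098,
        "F20-29": 893, "F40-49": 1961, "X71-83": 821, "X-SUBSTANCE-ABUSE": 314,
        "F80-89": 417, "F70-79": 813, "F60-69": 369, "T08-T14": 221,
        "X-TBI": 201, "F01-09": 580, "MED-ANTIDEPRESSANT": 114, "R40-46": 74,
        "MED-ANTIPSYCHOTIC": 13, "MED-ANTIANXIETY": 20, "G30-32": 47,
        "Q90-99": 32, "F50-59": 18, "G10-14": 6, "G00-99": 3,
    },
}

DEFAULT_SEX_WEIGHTS: dict[str, dict[str, float]] = {
    POI: {"male": 0.791, "female": 0.178, "unknown": 0.031},
    VICTIM: {"female": 0.747, "male": 0.231, "unknown": 0.022},
}

#: age-band weights per role; "unknown" leaves the age unset
DEFAULT_AGE_WEIGHTS: dict[str, dict[str, float]] = {
    POI: {
        "0-14": 0.004, "15-24": 0.17, "25-34": 0.30, "35-44": 0.27,
        "45-54": 0.16, "55-64": 0.07, "65+": 0.03, "unknown": 0.03,
    },
    VICTIM: {
        "0-14": 0.03, "15-24": 0.19, "25-34": 0.25, "35-44": 0.24,
        "45-54": 0.15, "55-64": 0.07, "65+": 0.055, "unknown": 0.015,
    },
}

_AGE_RANGES = {
    "0-14": (0, 14), "15-24": (15, 24), "25-34": (25, 34), "35-44": (35, 44),
    "45-54": (45, 54), "55-64": (55, 64), "65+": (65, 90),
}

# --------------------------------------------------------------------------
# sentence template banks
# --------------------------------------------------------------------------

ILLNESS_TEMPLATES = [
    "The {anchor} has been diagnosed with {term}.",
    "The {anchor} is suffering from {term}.",
    "The {anchor} suffers from {term}.",
    "The {anchor} has a history of {term}.",
    "The {anchor} has {term}.",
    "The {anchor} was diagnosed with {term} several years ago.",
    "Police were informed that the {anchor} suffers from {term}.",
    "It was reported that the {anchor} has {term}.",
    "The {anchor} disclosed a diagnosis of {term}.",
    "Family members stated the {anchor} has been treated for {term}.",
    "The {anchor} is known to have {term}.",
    "According to relatives the {anchor} has long standing {term}.",
]

MEDICATION_TEMPLATES = [
    "The {anchor} takes {term}.",
    "The {anchor} is on {term}.",
    "The {anchor} has been prescribed {term}.",
    "The {anchor} takes a number of {term}.",
    "The {anchor} stated they are on {term} for their nerves.",
    "Officers observed that the {anchor} is taking {term}.",
    "The {anchor} reported being prescribed {term} by their doctor.",
    "The {anchor} ran out of {term} last week.",
]

GENERIC_TEMPLATES = [
    "The {anchor} has {term}.",
    "Police noted the {anchor} has ongoing {term}.",
    "The {anchor} is suffering from {term}.",
]

#: neutral incident filler; a few use role anchors but none contain lexicon terms
FILLER_SENTENCES = [
    "Police attended the address following reports of a verbal argument.",
    "Police attended the location after a neighbour called triple zero.",
    "On arrival officers spoke with both parties separately.",
    "The argument began over a financial matter earlier in the evening.",
    "Officers conducted a walkthrough of the residence.",
    "Neighbours reported hearing shouting for approximately twenty minutes.",
    "No injuries were observed by the attending officers.",
    "An apprehended violence order application was initiated.",
    "Both parties were spoken to and advised regarding their options.",
    "The incident occurred in the kitchen of the shared residence.",
    "Police observed damage to a door inside the premises.",
    "The victim declined to provide a written statement.",
    "The POI left the scene prior to police arrival.",
    "The parties have been in a relationship for several years.",
]

#: illness term with no role anchor — must NOT be extracted
DISTRACTOR_TEMPLATES = [
    "A pamphlet about {term} was on the kitchen table.",
    "There was a flyer for a {term} support group on the fridge.",
    "A book about {term} was seen in the hallway.",
    "A community notice regarding {term} services was displayed nearby.",
]

_MULTI_PATTERNS = [(2, 1), (1, 2), (2, 2), (3, 1), (1, 3)]


class GeneratorConfig(BaseModel):
    """Knobs of the synthetic corpus; defaults emulate corpus-scale rates."""

    n_events: int = Field(default=2000, ge=0)
    seed: int = 0
    p_single: float = Field(default=0.846, ge=0, le=1)
    p_mention_poi: float = Field(default=0.128, ge=0, le=1)
    p_mention_victim: float = Field(default=0.037, ge=0, le=1)
    p_flag: float = Field(default=0.0103, ge=0, le=1)
    typo_rate: float = Field(default=0.10, ge=0, le=1)
    distractor_rate: float = Field(default=0.05, ge=0, le=1)
    #: probability of a 2nd / 3rd distinct-category mention given a 1st one
    p_second_mention: float = Field(default=0.22, ge=0, le=1)
    p_third_mention: float = Field(default=0.04, ge=0, le=1)
    #: mean events per pooled person, per role (controls id reuse)
    events_per_poi: float = Field(default=1.94, gt=0)
    events_per_victim: float = Field(default=1.71, gt=0)
    category_weights: Optional[dict[str, dict[str, float]]] = None
    sex_weights: Optional[dict[str, dict[str, float]]] = None
    age_weights: Optional[dict[str, dict[str, float]]] = None

    @field_validator("category_weights", "sex_weights", "age_weights")
    @classmethod
    def _nonnegative_weights(cls, v):
        if v is not None:
            for role, weights in v.items():
                if role not in (POI, VICTIM):
                    raise ValueError(f"weights keyed by unknown role {role!r}")
                if any(w < 0 for w in weights.values()):
                    raise ValueError("weights must be nonnegative")
                if sum(weights.values()) <= 0:
                    raise ValueError("weights must not all be zero")
        return v


@dataclass(frozen=True)
class GoldMention:
    role: str
    node_code: str
    surface: str
    template_id: str
    start: int
    end: int
    typo: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {
            "role": self.role, "node_code": self.node_code, "surface": self.surface,
            "template_id": self.template_id, "start": self.start, "end": self.end,
            "typo": self.typo,
        }


@dataclass
class GoldEvent:
    event_id: str
    single: bool
    mi_flag: bool
    mentions: list[GoldMention] = field(default_factory=list)
    n_distractors: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "event_id": self.event_id, "single": self.single, "mi_flag": self.mi_flag,
            "mentions": [m.to_dict() for m in self.mentions],
            "n_distractors": self.n_distractors,
        }


@dataclass(frozen=True)
class GoldPerson:
    person_id: str
    role: str
    has_mi: bool
    n_events: int
    sex: str
    age: Optional[int]

    def to_dict(self) -> dict[str, Any]:
        return {
            "person_id": self.person_id, "role": self.role, "has_mi": self.has_mi,
            "n_events": self.n_events, "sex": self.sex, "age": self.age,
        }


@dataclass
class GoldLedger:
    events: list[GoldEvent] = field(default_factory=list)
    persons: list[GoldPerson] = field(default_factory=list)

    def event_dicts(self) -> list[dict[str, Any]]:
        return [e.to_dict() for e in self.events]

    def person_dicts(self) -> list[dict[str, Any]]:
        return [p.to_dict() for p in self.persons]

    @classmethod
    def from_dicts(
        cls, event_dicts: list[dict[str, Any]], person_dicts: list[dict[str, Any]] | None = None
    ) -> "GoldLedger":
        events = [
            GoldEvent(
                event_id=d["event_id"], single=d["single"], mi_flag=d["mi_flag"],
                mentions=[GoldMention(**m) for m in d.get("mentions", [])],
                n_distractors=d.get("n_distractors", 0),
            )
            for d in event_dicts
        ]
        persons = [GoldPerson(**p) for p in (person_dicts or [])]
        return cls(events=events, persons=persons)


def _weighted_choice(rng: random.Random, weights: dict[str, float]) -> str:
    keys = sorted(weights)
    return rng.choices(keys, weights=[weights[k] for k in keys], k=1)[0]


def _render_anchor(token: str) -> str:
    return token.upper() if token in ("poi", "vic") else token


class _PersonPool:
    """Lazy pool of stable person ids with per-person demographics."""

    def __init__(self, prefix: str, size: int, role: str,
                 sex_weights: dict[str, float], age_weights: dict[str, float]):
        self.prefix, self.size, self.role = prefix, size, role
        self.sex_weights, self.age_weights = sex_weights, age_weights
        self._attrs: dict[int, tuple[str, Optional[int]]] = {}

    def draw(self, rng: random.Random) -> tuple[str, str, Optional[int]]:
        idx = rng.randrange(self.size)
        if idx not in self._attrs:
            sex = _weighted_choice(rng, self.sex_weights)
            band = _weighted_choice(rng, self.age_weights)
            age = None if band == "unknown" else rng.randint(*_AGE_RANGES[band])
            self._attrs[idx] = (sex, age)
        sex, age = self._attrs[idx]
        return f"{self.prefix}{idx:06d}", sex, age


def _plan_mentions(
    rng: random.Random,
    role: str,
    config: GeneratorConfig,
    weights: dict[str, float],
    entries_by_code: dict[str, list],
) -> list[tuple[str, Any]]:
    """Choose distinct-category lexicon entries to plant for one role."""
    k = 1
    if rng.random() < config.p_second_mention:
        k += 1
    if rng.random() < config.p_third_mention:
        k += 1
    chosen_codes: list[str] = []
    for _ in range(k):
        for _attempt in range(10):
            code = _weighted_choice(rng, weights)
            if code not in chosen_codes and entries_by_code.get(code):
                chosen_codes.append(code)
                break
    picks = []
    for code in chosen_codes:
        picks.append((code, rng.choice(entries_by_code[code])))
    return picks


def _mention_sentence(
    rng: random.Random, role: str, entry, config: GeneratorConfig, rules: RuleSet
) -> tuple[str, int, int, str, str, bool]:
    """Render one mention sentence; returns (text, rel_start, rel_end,
    surface, template_id, typo)."""
    if entry.entry_kind in ("medication_class", "medication_brand"):
        bank, tag = MEDICATION_TEMPLATES, "med"
    elif entry.entry_kind == "generic_illness":
        bank, tag = GENERIC_TEMPLATES, "gen"
    else:
        bank, tag = ILLNESS_TEMPLATES, "ill"
    t_idx = rng.randrange(len(bank))
    template = bank[t_idx]
    anchor = _render_anchor(rng.choice(rules.anchors[role]))
    surface = entry.surface
    typo = False
    if entry.variants and rng.random() < config.typo_rate:
        surface = rng.choice(sorted(entry.variants))
        typo = True
    before, after = template.split("{term}")
    before = before.format(anchor=anchor)
    text = before + surface + after
    return text, len(before), len(before) + len(surface), surface, f"{tag}{t_idx}", typo


def generate(
    config: GeneratorConfig,
    lexicon: Optional[Lexicon] = None,
    rules: Optional[RuleSet] = None,
) -> tuple[list[EventRecord], GoldLedger]:
    """Generate a corpus and its gold ledger, deterministically in the seed."""
    if lexicon is None:
        lexicon = default_lexicon()
    if rules is None:
        rules = default_rules()
    rng = random.Random(config.seed)

    # entries reachable under each weighted category code
    cat_weights = config.category_weights or DEFAULT_CATEGORY_WEIGHTS
    sex_weights = config.sex_weights or DEFAULT_SEX_WEIGHTS
    age_weights = config.age_weights or DEFAULT_AGE_WEIGHTS
    entries_by_code: dict[str, list] = {}
    all_codes = {c for w in cat_weights.values() for c in w}
    for code in sorted(all_codes):
        entries_by_code[code] = sorted(
            (
                e
                for e in lexicon.entries
                if code in {a.code for a in lexicon.hierarchy.ancestors(e.node_code)}
            ),
            key=lambda e: e.surface,
        )
    illness_surfaces = sorted(
        e.surface for e in lexicon.entries if e.entry_kind in ("illness", "generic_illness")
    )

    n_singles_expected = max(1.0, config.n_events * config.p_single)
    pools = {
        POI: _PersonPool("P", max(1, round(n_singles_expected / config.events_per_poi)),
                         POI, sex_weights[POI], age_weights[POI]),
        VICTIM: _PersonPool("V", max(1, round(n_singles_expected / config.events_per_victim)),
                            VICTIM, sex_weights[VICTIM], age_weights[VICTIM]),
    }

    events: list[EventRecord] = []
    gold = GoldLedger()
    person_events: dict[tuple[str, str], list[GoldEvent]] = {}
    person_attrs: dict[tuple[str, str], tuple[str, Optional[int]]] = {}

    for i in range(config.n_events):
        event_id = f"E{i:07d}"
        year = rng.randint(2005, 2016)
        single = rng.random() < config.p_single
        mi_flag = rng.random() < config.p_flag

        if single:
            n_pois = n_victims = 1
            poi_id, poi_sex, poi_age = pools[POI].draw(rng)
            victim_id, victim_sex, victim_age = pools[VICTIM].draw(rng)
        else:
            n_pois, n_victims = rng.choice(_MULTI_PATTERNS)
            poi_id = victim_id = None
            poi_sex = victim_sex = "unknown"
            poi_age = victim_age = None

        # plan gold mentions per role
        planted: list[tuple[str, Any]] = []
        if rng.random() < config.p_mention_poi:
            planted.extend((POI, e) for _, e in _plan_mentions(
                rng, POI, config, cat_weights[POI], entries_by_code))
        if rng.random() < config.p_mention_victim:
            planted.extend((VICTIM, e) for _, e in _plan_mentions(
                rng, VICTIM, config, cat_weights[VICTIM], entries_by_code))

        # render sentences
        opener_count = rng.randint(1, 2)
        openers = [rng.choice(FILLER_SENTENCES) for _ in range(opener_count)]
        middle: list[tuple[str, Optional[tuple[int, int, GoldMention]]]] = []
        for role, entry in planted:
            text, rs, re_, surface, template_id, typo = _mention_sentence(
                rng, role, entry, config, rules)
            gm = GoldMention(role=role, node_code=entry.node_code, surface=surface,
                             template_id=template_id, start=-1, end=-1, typo=typo)
            middle.append((text, (rs, re_, gm)))
        rng.shuffle(middle)
        n_distractors = 0
        if rng.random() < config.distractor_rate and illness_surfaces:
            term = rng.choice(illness_surfaces)
            d_text = rng.choice(DISTRACTOR_TEMPLATES).format(term=term)
            middle.insert(rng.randint(0, len(middle)), (d_text, None))
            n_distractors = 1
        closer = [rng.choice(FILLER_SENTENCES)]

        parts: list[str] = []
        gold_mentions: list[GoldMention] = []
        cursor = 0
        for text, info in [(t, None) for t in openers] + middle + [(t, None) for t in closer]:
            if info is not None:
                rs, re_, gm = info
                gold_mentions.append(
                    GoldMention(role=gm.role, node_code=gm.node_code, surface=gm.surface,
                                template_id=gm.template_id, start=cursor + rs,
                                end=cursor + re_, typo=gm.typo)
                )
            parts.append(text)
            cursor += len(text) + 1  # single-space joiner
        narrative = " ".join(parts)

        event = EventRecord(
            event_id=event_id, narrative=narrative, n_pois=n_pois, n_victims=n_victims,
            poi_id=poi_id, victim_id=victim_id, poi_sex=poi_sex, victim_sex=victim_sex,
            poi_age=poi_age, victim_age=victim_age, mi_flag=mi_flag, year=year,
        )
        gold_event = GoldEvent(event_id=event_id, single=single, mi_flag=mi_flag,
                               mentions=gold_mentions, n_distractors=n_distractors)
        events.append(event)
        gold.events.append(gold_event)

        if single:
            for role, pid, sex, age in (
                (POI, poi_id, poi_sex, poi_age), (VICTIM, victim_id, victim_sex, victim_age)
            ):
                person_events.setdefault((role, pid), []).append(gold_event)
                person_attrs[(role, pid)] = (sex, age)

    for (role, pid), evts in person_events.items():
        sex, age = person_attrs[(role, pid)]
        has_mi = any(m.role == role for e in evts for m in e.mentions)
        gold.persons.append(
            GoldPerson(person_id=pid, role=role, has_mi=has_mi, n_events=len(evts),
                       sex=sex, age=age)
        )
    return events, gold


def corpus_summary(gold: GoldLedger) -> dict[str, Optional[float]]:
    """Realized rates for each configured probability, for test assertions.

    Rates with a zero denominator are reported as ``None``.
    """
    n = len(gold.events)
    if n == 0:
        return {
            "realized_p_single": None, "realized_p_mention_poi": None,
            "realized_p_mention_victim": None, "realized_p_flag": None,
            "realized_distractor_rate": None, "realized_typo_rate": None,
            "n_events": 0, "n_gold_mentions": 0,
        }
    n_mentions = sum(len(e.mentions) for e in gold.events)
    n_typo = sum(1 for e in gold.events for m in e.mentions if m.typo)
    return {
        "realized_p_single": sum(e.single for e in gold.events) / n,
        "realized_p_mention_poi": sum(
            any(m.role == POI for m in e.mentions) for e in gold.events) / n,
        "realized_p_mention_victim": sum(
            any(m.role == VICTIM for m in e.mentions) for e in gold.events) / n,
        "realized_p_flag": sum(e.mi_flag for e in gold.events) / n,
        "realized_distractor_rate": sum(e.n_distractors > 0 for e in gold.events) / n,
        "realized_typo_rate": (n_typo / n_mentions) if n_mentions else None,
        "n_events": n,
        "n_gold_mentions": n_mentions,
    }
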