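"""Rule engine: detect illness/medication mentions and attribute them to roles.

Two ingredients drive extraction, mirroring the knowledge-driven design the
package implements:

* a dictionary of surface forms (:class:`~dvminer.lexicon.Lexicon`), and
* a declarative rule set of *semantic anchors* — role-denoting tokens such as
  "POI"/"defendant" for the person of interest and "victim"/"vic" for the
  victim — plus optional trigger phrases ("suffering from", "diagnosed with",
  "takes", ...).

Attribution is sentence-scoped: a dictionary hit in a sentence with no anchor
is ignored (extraction is precision-oriented), and a hit in an anchored
sentence is attributed to the nearest anchor by character distance, with ties
going to the anchor that precedes the hit.  Negation is deliberately not
handled; its cost is measurable through the evaluation module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional

import yaml

from .lexicon import Lexicon

__all__ = [
    "POI",
    "VICTIM",
    "EventRecord",
    "Mention",
    "RuleSet",
    "load_rules",
    "default_rules",
    "segment_sentences",
    "find_anchors",
    "extract_mentions",
    "extract_corpus",
]

POI = "POI"
VICTIM = "VICTIM"
ROLES = (POI, VICTIM)


@dataclass(frozen=True)
class EventRecord:
    """One police-recorded DV event: structured fixed fields plus narrative."""

    event_id: str
    narrative: str
    n_pois: int = 1
    n_victims: int = 1
    poi_id: Optional[str] = None
    victim_id: Optional[str] = None
    poi_sex: str = "unknown"
    victim_sex: str = "unknown"
    poi_age: Optional[int] = None
    victim_age: Optional[int] = None
    mi_flag: bool = False
    year: Optional[int] = None

    def __post_init__(self) -> None:
        for age in (self.poi_age, self.victim_age):
            if age is not None and not 0 <= age <= 120:
                raise ValueError(f"{self.event_id}: age {age} outside 0..120")
        if self.n_pois < 0 or self.n_victims < 0:
            raise ValueError(f"{self.event_id}: person counts must be nonnegative")

    def to_dict(self) -> dict[str, Any]:
        return {
            "event_id": self.event_id,
            "narrative": self.narrative,
            "n_pois": self.n_pois,
            "n_victims": self.n_victims,
            "poi_id": self.poi_id,
            "victim_id": self.victim_id,
            "poi_sex": self.poi_sex,
            "victim_sex": self.victim_sex,
            "poi_age": self.poi_age,
            "victim_age": self.victim_age,
            "mi_flag": self.mi_flag,
            "year": self.year,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "EventRecord":
        return cls(**{k: d.get(k) for k in cls.__dataclass_fields__ if k in d})


@dataclass(frozen=True)
class Mention:
    """An extracted illness/medication span attributed to a role."""

    event_id: str
    subject: str  # POI or VICTIM
    surface: str
    node_code: str
    span: tuple[int, int]  # 0-based half-open interval into the raw narrative
    anchor: str
    pattern_id: str

    def to_dict(self) -> dict[str, Any]:
        return {
            "event_id": self.event_id,
            "subject": self.subject,
            "surface": self.surface,
            "node_code": self.node_code,
            "start": self.span[0],
            "end": self.span[1],
            "anchor": self.anchor,
            "pattern_id": self.pattern_id,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Mention":
        return cls(
            event_id=d["event_id"],
            subject=d["subject"],
            surface=d["surface"],
            node_code=d["node_code"],
            span=(int(d["start"]), int(d["end"])),
            anchor=d.get("anchor", ""),
            pattern_id=d.get("pattern_id", ""),
        )


@dataclass
class RuleSet:
    """Anchor vocabulary per role plus an optional trigger-phrase lexicon."""

    anchors: dict[str, list[str]]
    triggers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.anchors or not any(self.anchors.values()):
            raise ValueError("rule set must define at least one anchor")
        unknown = set(self.anchors) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown roles in rule set: {sorted(unknown)}")
        self._anchor_res = {
            role: re.compile(
                r"\b(?:" + "|".join(re.escape(a) for a in sorted(toks, key=len, reverse=True)) + r")\b",
                re.IGNORECASE,
            )
            for role, toks in self.anchors.items()
            if toks
        }
        if self.triggers:
            # longest phrase first so e.g. "suffering from" wins over "has"
            items = sorted(self.triggers.items(), key=lambda kv: (-len(kv[1]), kv[0]))
            self._trigger_re = re.compile(
                "|".join(f"(?P<{tid}>\\b{re.escape(phrase)}\\b)" for tid, phrase in items),
                re.IGNORECASE,
            )
        else:
            self._trigger_re = None


def load_rules(path: str | Path) -> RuleSet:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RuleSet(anchors=raw.get("anchors", {}), triggers=raw.get("triggers", {}) or {})


def default_rules() -> RuleSet:
    from .lexicon import _data_path

    return load_rules(_data_path("rules.yaml"))


_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+")


def segment_sentences(narrative: str) -> list[tuple[int, int]]:
    """Split a narrative into sentence intervals (0-based, half-open).

    Boundaries are placed after ``.``/``!``/``?`` followed by whitespace.
    Returned intervals are disjoint, ordered, and cover every non-whitespace
    character; terminators stay inside their sentence.
    """
    spans: list[tuple[int, int]] = []
    cut = 0
    for m in _SENT_BOUNDARY.finditer(narrative):
        spans.append((cut, m.start()))
        cut = m.end()
    spans.append((cut, len(narrative)))
    # trim surrounding whitespace and drop empty segments
    out: list[tuple[int, int]] = []
    for s, e in spans:
        seg = narrative[s:e]
        ls = len(seg) - len(seg.lstrip())
        rs = len(seg) - len(seg.rstrip())
        if s + ls < e - rs:
            out.append((s + ls, e - rs))
    return out


def find_anchors(sentence: str, rules: Optional[RuleSet] = None) -> list[tuple[str, tuple[int, int]]]:
    """Every word-boundary occurrence of a role anchor, ordered by position."""
    if rules is None:
        rules = default_rules()
    hits: list[tuple[str, tuple[int, int]]] = []
    for role, rx in rules._anchor_res.items():
        for m in rx.finditer(sentence):
            hits.append((role, (m.start(), m.end())))
    hits.sort(key=lambda h: h[1])
    return hits


def _nearest_anchor(
    anchors: list[tuple[str, tuple[int, int]]], start: int, end: int
) -> tuple[str, tuple[int, int]]:
    """Nearest anchor by character distance; ties favour a preceding anchor."""
    def dist(span: tuple[int, int]) -> int:
        a_s, a_e = span
        if a_e <= start:
            return start - a_e
        if a_s >= end:
            return a_s - end
        return 0  # overlapping (should not happen: anchors are not lexicon terms)

    return min(anchors, key=lambda h: (dist(h[1]), 0 if h[1][1] <= start else 1, h[1][0]))


def extract_mentions(event: EventRecord, lexicon: Lexicon, rules: RuleSet) -> list[Mention]:
    """Extract attributed mentions from one event narrative.

    Within one event, duplicate ``(subject, node_code)`` pairs are collapsed to
    the first occurrence, so repeating "depression" for the POI yields a single
    mention while two *different* conditions yield two.
    """
    narrative = event.narrative
    lex_re = lexicon.pattern()
    mentions: list[Mention] = []
    seen: set[tuple[str, str]] = set()
    for s_start, s_end in segment_sentences(narrative):
        sentence = narrative[s_start:s_end]
        anchors = find_anchors(sentence, rules)
        if not anchors:
            continue
        triggers = (
            [(m.lastgroup, m.span()) for m in rules._trigger_re.finditer(sentence)]
            if rules._trigger_re is not None
            else []
        )
        for m in lex_re.finditer(sentence):
            surface = m.group(0)
            entry = lexicon.lookup(re.sub(r"\s+", " ", surface))
            if entry is None:  # pragma: no cover - pattern and lookup share forms
                continue
            role, a_span = _nearest_anchor(anchors, m.start(), m.end())
            trig_id = None
            for tid, (t_s, t_e) in triggers:
                if t_e <= m.start():
                    trig_id = tid  # last trigger ending before the hit
            pattern_id = f"{role.lower()}:{trig_id or 'anchor_only'}"
            key = (role, entry.node_code)
            if key in seen:
                continue
            seen.add(key)
            mentions.append(
                Mention(
                    event_id=event.event_id,
                    subject=role,
                    surface=surface,
                    node_code=entry.node_code,
                    span=(s_start + m.start(), s_start + m.end()),
                    anchor=sentence[a_span[0] : a_span[1]],
                    pattern_id=pattern_id,
                )
            )
    return mentions


def extract_corpus(
    events: Iterable[EventRecord], lexicon: Lexicon, rules: RuleSet
) -> list[Mention]:
    """Run the rule engine over a corpus, preserving event order."""
    out: list[Mention] = []
    for event in events:
        out.extend(extract_mentions(event, lexicon, rules))
    return out
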