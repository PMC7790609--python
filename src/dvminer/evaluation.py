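"""Score extraction output against a gold ledger.

The headline metric is precision — the fraction of extracted mentions that
are correct — complemented by recall and F1, split by role.  Matching is
greedy one-to-one in document order on ``(event_id, subject, level-1 code)``
by default, so credit is judged on whether the right kind of condition was
attributed to the right person, not on code depth; ``match_mode="exact"``
tightens the key to the exact node code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Optional, Sequence

from .extraction import POI, VICTIM, Mention
from .lexicon import Hierarchy
from .synthetic_data import GoldLedger

__all__ = ["RoleScore", "EvalResult", "score"]


@dataclass(frozen=True)
class RoleScore:
    true_positive: int
    false_positive: int
    false_negative: int

    @property
    def precision(self) -> Optional[float]:
        d = self.true_positive + self.false_positive
        return round(self.true_positive / d, 4) if d else None

    @property
    def recall(self) -> Optional[float]:
        d = self.true_positive + self.false_negative
        return round(self.true_positive / d, 4) if d else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return round(2 * p * r / (p + r), 4)

    def to_dict(self) -> dict[str, Any]:
        return {
            "true_positive": self.true_positive,
            "false_positive": self.false_positive,
            "false_negative": self.false_negative,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass(frozen=True)
class EvalResult:
    overall: RoleScore
    per_role: dict[str, RoleScore]

    def to_dict(self) -> dict[str, Any]:
        return {
            "overall": self.overall.to_dict(),
            "per_role": {role: s.to_dict() for role, s in self.per_role.items()},
        }


def _match_key(event_id: str, subject: str, node_code: str,
               hierarchy: Hierarchy, match_mode: str) -> tuple[str, str, str]:
    if match_mode == "level1":
        node_code = hierarchy.root_of(node_code).code
    elif match_mode != "exact":
        raise ValueError(f"match_mode must be 'level1' or 'exact', got {match_mode!r}")
    return (event_id, subject, node_code)


def score(
    predicted: Sequence[Mention],
    gold: GoldLedger,
    hierarchy: Hierarchy,
    match_mode: str = "level1",
) -> EvalResult:
    """Compare predicted mentions with the gold ledger of the same corpus.

    A prediction is a true positive iff a not-yet-matched gold mention shares
    its matching key; matching is one-to-one and greedy in document order, so
    a gold mention can credit at most one prediction.
    """
    gold_event_ids = {e.event_id for e in gold.events}
    unknown = {m.event_id for m in predicted} - gold_event_ids
    if unknown:
        raise ValueError(
            f"predictions refer to events absent from the gold ledger: {sorted(unknown)[:5]}"
        )

    budget: dict[tuple[str, str, str], int] = {}
    gold_by_role = {POI: 0, VICTIM: 0}
    for ev in gold.events:
        for gm in ev.mentions:
            key = _match_key(ev.event_id, gm.role, gm.node_code, hierarchy, match_mode)
            budget[key] = budget.get(key, 0) + 1
            gold_by_role[gm.role] += 1

    tp = {POI: 0, VICTIM: 0}
    fp = {POI: 0, VICTIM: 0}
    for m in predicted:
        key = _match_key(m.event_id, m.subject, m.node_code, hierarchy, match_mode)
        if budget.get(key, 0) > 0:
            budget[key] -= 1
            tp[m.subject] += 1
        else:
            fp[m.subject] += 1

    per_role = {
        role: RoleScore(
            true_positive=tp[role],
            false_positive=fp[role],
            false_negative=gold_by_role[role] - tp[role],
        )
        for role in (POI, VICTIM)
    }
    overall = RoleScore(
        true_positive=tp[POI] + tp[VICTIM],
        false_positive=fp[POI] + fp[VICTIM],
        false_negative=(gold_by_role[POI] - tp[POI]) + (gold_by_role[VICTIM] - tp[VICTIM]),
    )
    return EvalResult(overall=overall, per_role=per_role)
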