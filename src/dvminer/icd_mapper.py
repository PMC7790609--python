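"""Normalize extracted mentions onto the code hierarchy.

A mention's lexicon entry resolves to a node at some depth 1..4.  For
reporting, level 4 is folded into level 3 (e.g. "intermittent explosive
disorder", a level-4 rubric, is reported under its level-3 "other impulse
disorders" parent's slot as the more specific label).  A mention therefore
*counts* at a level iff its entry's depth reaches that level, which makes the
per-level totals weakly decreasing from level 1 to level 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .extraction import Mention
from .lexicon import Hierarchy

__all__ = ["LeveledMention", "normalize", "normalize_all", "level_counts", "to_frame"]


@dataclass(frozen=True)
class LeveledMention:
    event_id: str
    subject: str
    level1_code: str
    level2_code: Optional[str] = None
    level3_code: Optional[str] = None

    def depth(self) -> int:
        if self.level3_code is not None:
            return 3
        if self.level2_code is not None:
            return 2
        return 1


def normalize(mention: Mention, hierarchy: Hierarchy) -> LeveledMention:
    """Resolve a mention's code to its level-1/2/3 memberships.

    Pure and idempotent: the result depends only on the mention's node code
    and the hierarchy.  A level-4 node reports its level-3 ancestor; a node
    that is only level 1 (the medication groups, traumatic brain injury,
    "unspecified mental disorder", ...) leaves levels 2 and 3 empty.
    """
    chain = hierarchy.ancestors(mention.node_code)
    return LeveledMention(
        event_id=mention.event_id,
        subject=mention.subject,
        level1_code=chain[0].code,
        level2_code=chain[1].code if len(chain) >= 2 else None,
        level3_code=chain[2].code if len(chain) >= 3 else None,
    )


def normalize_all(mentions: Iterable[Mention], hierarchy: Hierarchy) -> list[LeveledMention]:
    return [normalize(m, hierarchy) for m in mentions]


def level_counts(
    mentions: Iterable[LeveledMention], subject_filter: Optional[str] = None
) -> tuple[int, int, int]:
    """Per-level mention totals ``(n_level1, n_level2, n_level3)``.

    Every mention counts at level 1; a mention counts at level 2/3 only when
    its entry is specific enough to reach that depth, hence
    ``n_level3 <= n_level2 <= n_level1``.
    """
    n1 = n2 = n3 = 0
    for m in mentions:
        if subject_filter is not None and m.subject != subject_filter:
            continue
        n1 += 1
        if m.level2_code is not None:
            n2 += 1
        if m.level3_code is not None:
            n3 += 1
    return n1, n2, n3


def to_frame(mentions: Iterable[LeveledMention]) -> pd.DataFrame:
    """Leveled mentions as a DataFrame (event_id, subject, level1, level2, level3)."""
    return pd.DataFrame(
        [
            {
                "event_id": m.event_id,
                "subject": m.subject,
                "level1": m.level1_code,
                "level2": m.level2_code,
                "level3": m.level3_code,
            }
            for m in mentions
        ],
        columns=["event_id", "subject", "level1", "level2", "level3"],
    )
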