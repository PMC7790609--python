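"""Illness/medication dictionaries and the 4-level ICD-10-derived hierarchy.

The hierarchy has 26 level-1 categories: 18 derived from ICD-10 chapter blocks
(e.g. ``F30-39`` mood disorders) plus 8 custom categories — four medication
groups (antianxiety, antidepressants, neuroleptics, antipsychotics) and four
non-ICD buckets (drug-prescription abuse, substance abuse unspecified,
traumatic brain injury, unspecified drug-induced disorders).  Custom codes use
an ``X-``/``MED-`` prefix namespace so they can never collide with real ICD
codes.

Both the hierarchy and the surface-form dictionary are shipped as plain
tab-separated files under ``dvminer/data`` so domain experts can extend them
without touching code.  Matching is case-insensitive after lowercasing; there
is no stemming and no edit-distance correction — misspellings are handled only
through explicit variants, which keeps precision auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "ICDNode",
    "LexiconEntry",
    "Hierarchy",
    "Lexicon",
    "HierarchyError",
    "LexiconError",
    "load_hierarchy",
    "save_hierarchy",
    "load_lexicon",
    "default_hierarchy",
    "default_lexicon",
]

ENTRY_KINDS = {"illness", "medication_class", "medication_brand", "generic_illness"}

#: level-1 code of the generic "unspecified mental disorder" bucket
UNSPECIFIED_CODE = "F99"

#: the four medication-group level-1 codes
MEDICATION_GROUP_CODES = {
    "MED-ANTIANXIETY",
    "MED-ANTIDEPRESSANT",
    "MED-NEUROLEPTIC",
    "MED-ANTIPSYCHOTIC",
}


class HierarchyError(ValueError):
    """A structural or validation problem in the code hierarchy."""


class LexiconError(ValueError):
    """A surface-form entry that cannot be resolved or validated."""


@dataclass(frozen=True)
class ICDNode:
    code: str
    label: str
    level: int
    parent: Optional[str] = None
    custom: bool = False


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    canonical: str
    node_code: str
    entry_kind: str
    variants: frozenset[str] = field(default_factory=frozenset)

    def forms(self) -> set[str]:
        return {self.surface, *self.variants}


class Hierarchy:
    """Validated forest of :class:`ICDNode` keyed by code."""

    def __init__(self, nodes: Iterable[ICDNode]):
        self._nodes: dict[str, ICDNode] = {}
        for node in nodes:
            if node.code in self._nodes:
                raise HierarchyError(f"duplicate code: {node.code!r}")
            if not 1 <= node.level <= 4:
                raise HierarchyError(f"{node.code!r}: level must be 1..4, got {node.level}")
            self._nodes[node.code] = node
        for node in self._nodes.values():
            if node.level == 1:
                if node.parent:
                    raise HierarchyError(f"level-1 node {node.code!r} must not have a parent")
                continue
            if not node.parent:
                raise HierarchyError(f"non-root node {node.code!r} has no parent")
            parent = self._nodes.get(node.parent)
            if parent is None:
                raise HierarchyError(f"orphan node {node.code!r}: parent {node.parent!r} not found")
            if parent.level != node.level - 1:
                raise HierarchyError(
                    f"{node.code!r} (level {node.level}) has parent {parent.code!r} "
                    f"of level {parent.level}; expected level {node.level - 1}"
                )

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, code: str) -> bool:
        return code in self._nodes

    def __getitem__(self, code: str) -> ICDNode:
        try:
            return self._nodes[code]
        except KeyError:
            raise KeyError(f"unknown hierarchy code: {code!r}") from None

    def nodes(self) -> list[ICDNode]:
        return list(self._nodes.values())

    def roots(self) -> list[ICDNode]:
        return [n for n in self._nodes.values() if n.level == 1]

    def ancestors(self, code: str) -> list[ICDNode]:
        """Path from the level-1 root down to ``code`` itself (length == level)."""
        node = self[code]
        path = [node]
        while node.parent is not None:
            node = self[node.parent]
            path.append(node)
        path.reverse()
        return path

    def root_of(self, code: str) -> ICDNode:
        return self.ancestors(code)[0]


def load_hierarchy(path: str | Path) -> Hierarchy:
    """Load and validate a hierarchy TSV (code/label/level/parent/custom)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"code", "label", "level", "parent", "custom"}
    missing = required - set(df.columns)
    if missing:
        raise HierarchyError(f"hierarchy file missing columns: {sorted(missing)}")
    nodes = [
        ICDNode(
            code=row.code.strip(),
            label=row.label.strip(),
            level=int(row.level),
            parent=row.parent.strip() or None,
            custom=str(row.custom).strip().lower() in {"true", "1", "yes"},
        )
        for row in df.itertuples(index=False)
    ]
    return Hierarchy(nodes)


def save_hierarchy(hierarchy: Hierarchy, path: str | Path) -> None:
    rows = [
        {
            "code": n.code,
            "label": n.label,
            "level": n.level,
            "parent": n.parent or "",
            "custom": "true" if n.custom else "false",
        }
        for n in hierarchy.nodes()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class Lexicon:
    """Surface-form dictionary with case-insensitive exact lookup."""

    def __init__(self, entries: Iterable[LexiconEntry], hierarchy: Hierarchy):
        self.hierarchy = hierarchy
        self.entries: list[LexiconEntry] = []
        self._by_form: dict[str, LexiconEntry] = {}
        for entry in entries:
            if entry.entry_kind not in ENTRY_KINDS:
                raise LexiconError(f"{entry.surface!r}: unknown entry_kind {entry.entry_kind!r}")
            if entry.node_code not in hierarchy:
                raise LexiconError(
                    f"{entry.surface!r}: node_code {entry.node_code!r} not in hierarchy"
                )
            if entry.entry_kind == "generic_illness" and entry.node_code != UNSPECIFIED_CODE:
                raise LexiconError(
                    f"{entry.surface!r}: generic_illness entries must map to {UNSPECIFIED_CODE}"
                )
            if entry.entry_kind == "medication_brand":
                root = hierarchy.root_of(entry.node_code).code
                if root not in MEDICATION_GROUP_CODES:
                    raise LexiconError(
                        f"{entry.surface!r}: medication_brand must map under a medication group"
                    )
            self.entries.append(entry)
            for form in entry.forms():
                key = form.lower()
                if key in self._by_form:
                    raise LexiconError(f"surface form {form!r} appears in multiple entries")
                self._by_form[key] = entry
        self._pattern: Optional[re.Pattern[str]] = None

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, surface: str) -> Optional[LexiconEntry]:
        return self._by_form.get(surface.strip().lower())

    def all_forms(self) -> list[str]:
        return sorted(self._by_form)

    def pattern(self) -> re.Pattern[str]:
        """Compiled alternation over every form, longest-first so overlapping
        shorter hits are suppressed (e.g. "paranoid schizophrenia" beats
        "schizophrenia")."""
        if self._pattern is None:
            forms = sorted(self._by_form, key=lambda f: (-len(f), f))
            alt = "|".join(re.escape(f).replace("\\ ", r"\s+") for f in forms)
            self._pattern = re.compile(rf"\b(?:{alt})\b", re.IGNORECASE)
        return self._pattern


def load_lexicon(path: str | Path, hierarchy: Hierarchy) -> Lexicon:
    """Load a surface-form TSV (surface/node_code/entry_kind/variants)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"surface", "node_code", "entry_kind", "variants"}
    missing = required - set(df.columns)
    if missing:
        raise LexiconError(f"surface-form file missing columns: {sorted(missing)}")
    entries = []
    for row in df.itertuples(index=False):
        node_code = row.node_code.strip()
        canonical = hierarchy[node_code].label if node_code in hierarchy else node_code
        variants = frozenset(
            v.strip().lower() for v in row.variants.split("|") if v.strip()
        )
        entries.append(
            LexiconEntry(
                surface=row.surface.strip().lower(),
                canonical=canonical,
                node_code=node_code,
                entry_kind=row.entry_kind.strip(),
                variants=variants,
            )
        )
    return Lexicon(entries, hierarchy)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("dvminer").joinpath("data", name)))


def default_hierarchy() -> Hierarchy:
    """The hierarchy shipped with the package."""
    return load_hierarchy(_data_path("hierarchy.tsv"))


def default_lexicon(hierarchy: Optional[Hierarchy] = None) -> Lexicon:
    """The seed dictionary shipped with the package (paper-scale coverage of
    conditions, drug classes and brand names; not a full ICD-10 terminology)."""
    if hierarchy is None:
        hierarchy = default_hierarchy()
    return load_lexicon(_data_path("surface_forms.tsv"), hierarchy)
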