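"""COG functional-class abundance profiles and strain-group contrasts.

Abundance of a COG class in a scope (a pan-proteome category or a strain
group) is the percentage of the scope's annotated proteins carrying that
class. Two denominator conventions are supported: ``"scope"`` (default; total
annotated proteins in the scope, so abundances are comparable across scopes
and self-contained) and ``"family_total"`` (the class's total protein count
across all analyzed proteomes). Fold-abundance ratios between two scopes are
invariant to any per-class-constant denominator, so contrasts such as a
4.28-fold enrichment of cell wall/membrane/envelope biogenesis (class M)
proteins are insensitive to this choice.

``group_exclusive`` finds orthogroups present in every strain of one group and
absent from every strain of another — the discovery step for proteins private
to, e.g., cholesterol-assimilating strains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .orthogroups import Orthogroup, PresenceAbsenceMatrix
from .partition import PartitionLabel, round_half_up

ABUNDANCE_COLUMNS = [
    "cog_class",
    "scope",
    "gene_count",
    "scope_total",
    "family_total",
    "abundance_pct",
]

_PARTITION_SCOPES = {lab.value for lab in PartitionLabel}


def _proteins_in_scope(
    orthogroups: Sequence[Orthogroup],
    labels: Mapping[str, PartitionLabel],
    scope: str,
    groups: Optional[Mapping[str, Iterable[str]]],
    restrict_to: Optional[str],
):
    """Yield the member proteins belonging to a scope.

    Partition scopes take all members of orthogroups with that label. Group
    scopes take members belonging to the group's strains, optionally restricted
    to orthogroups of one partition label (e.g. the accessory proteome only).
    """
    if scope in _PARTITION_SCOPES:
        for og in orthogroups:
            if labels[og.orthogroup_id].value == scope:
                yield from og.members
        return
    if groups and scope in groups:
        strains = set(groups[scope])
        for og in orthogroups:
            if restrict_to is not None and labels[og.orthogroup_id].value != restrict_to:
                continue
            for m in og.members:
                if m.strain_id in strains:
                    yield m
        return
    raise ValueError(f"unknown scope {scope!r}")


def abundance(
    orthogroups: Sequence[Orthogroup],
    labels: Mapping[str, PartitionLabel],
    scope: str,
    groups: Optional[Mapping[str, Iterable[str]]] = None,
    restrict_to: Optional[str] = None,
    denominator: str = "scope",
) -> pd.DataFrame:
    """Per-COG-class abundance table for one scope.

    Returns a DataFrame with columns ``cog_class, scope, gene_count,
    scope_total, family_total, abundance_pct``; one row per class observed in
    the analyzed proteomes (so tables from different scopes align row-wise).
    Unannotated proteins count toward no class and no denominator.
    """
    if denominator not in ("scope", "family_total"):
        raise ValueError(f"unknown denominator convention {denominator!r}")

    family_total: dict[str, int] = {}
    for og in orthogroups:
        for m in og.members:
            if m.cog_class:
                family_total[m.cog_class] = family_total.get(m.cog_class, 0) + 1

    in_scope = list(_proteins_in_scope(orthogroups, labels, scope, groups, restrict_to))
    scope_counts: dict[str, int] = {}
    for m in in_scope:
        if m.cog_class:
            scope_counts[m.cog_class] = scope_counts.get(m.cog_class, 0) + 1
    scope_total = sum(scope_counts.values())

    rows = []
    for cls in sorted(family_total):
        count = scope_counts.get(cls, 0)
        denom = scope_total if denominator == "scope" else family_total[cls]
        pct = 100.0 * count / denom if denom else 0.0
        rows.append((cls, scope, count, scope_total, family_total[cls], pct))
    return pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS)


def fold_abundance(
    table_a: pd.DataFrame, table_b: pd.DataFrame, cog_class: str
) -> float:
    """Ratio of a COG class's abundance between two scopes.

    ``abundance_pct(a) / abundance_pct(b)``; a zero denominator yields
    ``math.inf`` (flagged infinite ratio) rather than an exception. The ratio
    is dimensionless and, for the same denominator convention, independent of
    any per-class-constant scaling.
    """
    def _get(table: pd.DataFrame, which: str) -> float:
        sel = table[table["cog_class"] == cog_class]
        if sel.empty:
            raise KeyError(f"class {cog_class!r} not present in table {which}")
        return float(sel["abundance_pct"].iloc[0])

    num = _get(table_a, "a")
    den = _get(table_b, "b")
    if den == 0.0:
        return math.inf
    return num / den


@dataclass
class GroupContrastResult:
    """Orthogroups present in every group_a strain and absent from group_b."""

    group_a: frozenset[str]
    group_b: frozenset[str]
    exclusive_orthogroups: list[str]

    @property
    def count(self) -> int:
        return len(self.exclusive_orthogroups)

    def to_dict(self) -> dict:
        return {
            "group_a": sorted(self.group_a),
            "group_b": sorted(self.group_b),
            "exclusive_orthogroups": list(self.exclusive_orthogroups),
            "count": self.count,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"orthogroup_id": self.exclusive_orthogroups})


def group_exclusive(
    matrix: PresenceAbsenceMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> GroupContrastResult:
    """Find orthogroups exclusive to ``group_a`` relative to ``group_b``.

    An orthogroup qualifies when present in *every* group_a strain and absent
    from *every* group_b strain; strains outside both groups are ignored.
    Groups must be disjoint, non-empty subsets of the matrix strains.
    """
    a = frozenset(group_a)
    b = frozenset(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if a & b:
        raise ValueError(f"groups overlap: {sorted(a & b)}")
    known = set(matrix.strain_ids)
    stray = (a | b) - known
    if stray:
        raise ValueError(f"group strains not in matrix: {sorted(stray)}")

    presence = matrix.presence
    mask = presence[sorted(a)].all(axis=1) & ~presence[sorted(b)].any(axis=1)
    ids = [og for og, hit in mask.items() if hit]
    return GroupContrastResult(group_a=a, group_b=b, exclusive_orthogroups=ids)
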