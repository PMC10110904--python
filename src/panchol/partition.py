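"""Core / accessory / unique partition of a pan-proteome.

A gene family (orthogroup) is *core* when present in every analyzed strain,
*unique* when present in exactly one, and *accessory* otherwise. Presence, not
copy number, drives the label: a family present in one strain with two copies
is still unique. Protein counts per category are sums of copy numbers over the
category's orthogroups.

Percentages are reported half-up to one decimal place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping

import pandas as pd

from .orthogroups import PresenceAbsenceMatrix


class PartitionLabel(str, Enum):
    CORE = "core"
    ACCESSORY = "accessory"
    UNIQUE = "unique"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 23.05 -> 23.1, not banker's 23.0)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(part: int, total: int, decimals: int = 1) -> float:
    """100 * part / total, half-up to ``decimals`` places."""
    if total <= 0:
        raise ValueError("percentage of an empty total is undefined")
    return round_half_up(100.0 * part / total, decimals)


def classify(matrix: PresenceAbsenceMatrix) -> dict[str, PartitionLabel]:
    """Label every orthogroup by its strain occupancy.

    Presence in all n strains -> core; in exactly one -> unique; otherwise
    accessory. Requires at least two strains and a non-empty matrix.
    """
    if len(matrix) == 0:
        raise ValueError("cannot classify an empty presence/absence matrix")
    n = len(matrix.strain_ids)
    if n < 2:
        raise ValueError("partition labels need at least two strains")
    occupancy = matrix.presence.sum(axis=1)
    labels: dict[str, PartitionLabel] = {}
    for og_id, k in occupancy.items():
        if k == n:
            labels[og_id] = PartitionLabel.CORE
        elif k == 1:
            labels[og_id] = PartitionLabel.UNIQUE
        else:
            labels[og_id] = PartitionLabel.ACCESSORY
    return labels


@dataclass
class PanPartitionSummary:
    """All partition-level statistics of one pan-proteome analysis.

    ``clusters``/``cluster_pct`` count orthogroups; ``proteins`` sums copy
    numbers; ``strain_specific`` gives, per strain, the summed copy numbers of
    the unique-category orthogroups private to that strain. Core orthogroups
    split into single-copy (copy number 1 in every strain) and multi-copy.
    """

    n_strains: int
    clusters: dict[str, int]
    cluster_pct: dict[str, float]
    proteins: dict[str, int]
    strain_specific: dict[str, int]
    core_single_copy: int
    core_multi_copy: int

    @property
    def n_clusters_total(self) -> int:
        return sum(self.clusters.values())

    def validate(self) -> None:
        if self.core_single_copy + self.core_multi_copy != self.clusters["core"]:
            raise ValueError("core single+multi copy counts do not sum to core clusters")
        if sum(self.strain_specific.values()) != self.proteins["unique"]:
            raise ValueError("strain-specific counts do not sum to unique proteins")
        if abs(sum(self.cluster_pct.values()) - 100.0) > 0.2:
            raise ValueError("cluster percentages do not sum to ~100")

    def to_dict(self) -> dict:
        return {
            "n_strains": self.n_strains,
            "clusters": dict(self.clusters),
            "cluster_pct": dict(self.cluster_pct),
            "proteins": dict(self.proteins),
            "strain_specific": dict(self.strain_specific),
            "core_single_copy": self.core_single_copy,
            "core_multi_copy": self.core_multi_copy,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanPartitionSummary":
        return cls(
            n_strains=int(d["n_strains"]),
            clusters={k: int(v) for k, v in d["clusters"].items()},
            cluster_pct={k: float(v) for k, v in d["cluster_pct"].items()},
            proteins={k: int(v) for k, v in d["proteins"].items()},
            strain_specific={k: int(v) for k, v in d["strain_specific"].items()},
            core_single_copy=int(d["core_single_copy"]),
            core_multi_copy=int(d["core_multi_copy"]),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in ("core", "accessory", "unique"):
            rows.append(
                {
                    "category": label,
                    "clusters": self.clusters[label],
                    "cluster_pct": self.cluster_pct[label],
                    "proteins": self.proteins[label],
                }
            )
        return pd.DataFrame(rows)


def summarize(
    matrix: PresenceAbsenceMatrix, labels: Mapping[str, PartitionLabel]
) -> PanPartitionSummary:
    """Aggregate a labelled matrix into a :class:`PanPartitionSummary`."""
    ids = set(matrix.orthogroup_ids)
    if set(labels) != ids:
        raise ValueError("labels do not cover exactly the matrix orthogroups")

    counts = matrix.counts
    presence = matrix.presence
    total = len(matrix)
    label_series = pd.Series({k: v.value for k, v in labels.items()}).loc[counts.index]

    clusters = {
        lab.value: int((label_series == lab.value).sum()) for lab in PartitionLabel
    }
    cluster_pct = {
        lab: percentage(cnt, total) for lab, cnt in clusters.items()
    }
    proteins = {
        lab.value: int(counts[label_series == lab.value].to_numpy().sum())
        for lab in PartitionLabel
    }

    unique_rows = counts[label_series == PartitionLabel.UNIQUE.value]
    strain_specific = {s: 0 for s in matrix.strain_ids}
    for og_id, row in unique_rows.iterrows():
        present = row[row > 0]
        strain = present.index[0]
        strain_specific[strain] += int(row.sum())

    core_rows = counts[label_series == PartitionLabel.CORE.value]
    single_mask = (core_rows == 1).all(axis=1)
    core_single = int(single_mask.sum())
    core_multi = int(len(core_rows) - core_single)

    summary = PanPartitionSummary(
        n_strains=len(matrix.strain_ids),
        clusters=clusters,
        cluster_pct=cluster_pct,
        proteins=proteins,
        strain_specific=strain_specific,
        core_single_copy=core_single,
        core_multi_copy=core_multi,
    )
    summary.validate()
    return summary
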