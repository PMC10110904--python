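"""Marker-gene presence screening against a proteome.

A marker panel is a curated list of protein sequences (probiotic trait genes
such as *bsh*, *dltA*, *gadC*; bacteriocins such as enterocin A/B) with a
free-text category. A marker counts as present when the best-scoring local
alignment against the proteome exceeds the identity threshold (strict >,
default 85%) at, effectively, full query coverage. "Full coverage" defaults to
>= 99.5% to tolerate terminal-residue trimming by the local aligner (the best
local alignment always drops a mismatching terminal residue); an exact-100
mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .align import AlignParams, align_pair
from .io import ProteinRecord, StrainProteome, _iter_fasta, logger


@dataclass(frozen=True)
class MarkerGene:
    """One marker: id, amino-acid sequence, free-text functional category."""

    marker_id: str
    sequence: str
    category: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"marker {self.marker_id!r}: empty sequence")


@dataclass(frozen=True)
class MarkerHit:
    """Screen outcome for one marker; hit fields are None when absent."""

    marker_id: str
    category: str
    present: bool
    best_hit: Optional[str] = None
    identity_pct: Optional[float] = None
    query_coverage_pct: Optional[float] = None


@dataclass
class ScreenResult:
    """Per-marker presence calls for one strain's proteome."""

    strain_id: str
    hits: list[MarkerHit]
    min_identity_pct: float
    min_query_coverage_pct: float

    @property
    def present_markers(self) -> list[str]:
        return [h.marker_id for h in self.hits if h.present]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.hits:
            rows.append(
                {
                    "marker_id": h.marker_id,
                    "category": h.category,
                    "present": h.present,
                    "best_hit": h.best_hit or "",
                    "identity_pct": "" if h.identity_pct is None else f"{h.identity_pct:.2f}",
                    "query_coverage_pct": ""
                    if h.query_coverage_pct is None
                    else f"{h.query_coverage_pct:.2f}",
                }
            )
        return pd.DataFrame(rows)


def read_panel(
    fasta_path: str | Path, category_tsv_path: Optional[str | Path] = None
) -> list[MarkerGene]:
    """Read a marker panel FASTA plus optional ``marker_id<TAB>category`` table."""
    categories: dict[str, str] = {}
    if category_tsv_path is not None:
        df = pd.read_csv(category_tsv_path, sep="\t", dtype=str, keep_default_na=False)
        if not {"marker_id", "category"} <= set(df.columns):
            raise ValueError("panel TSV needs columns marker_id, category")
        categories = dict(zip(df["marker_id"], df["category"]))
    panel: list[MarkerGene] = []
    seen: set[str] = set()
    for header, seq, _ in _iter_fasta(fasta_path):
        if header in seen:
            raise ValueError(f"duplicate marker id {header!r} in panel")
        seen.add(header)
        panel.append(
            MarkerGene(marker_id=header, sequence=seq, category=categories.get(header, ""))
        )
    return panel


def screen(
    proteome: StrainProteome | Sequence[ProteinRecord],
    panel: Sequence[MarkerGene],
    min_identity_pct: float = 85.0,
    min_query_coverage_pct: float = 99.5,
    exact_coverage: bool = False,
    params: AlignParams = AlignParams(),
) -> ScreenResult:
    """Screen a marker panel against one proteome.

    For each marker the best-scoring proteome protein (by local alignment
    score) is evaluated: present iff identity_pct > ``min_identity_pct`` and
    query coverage >= ``min_query_coverage_pct`` (== 100 with
    ``exact_coverage``). The marker is the query, i.e. the coverage reference.
    Raising either threshold can only switch markers from present to absent.
    """
    if not panel:
        raise ValueError("marker panel is empty")
    if not 0.0 <= min_identity_pct <= 100.0 or not 0.0 <= min_query_coverage_pct <= 100.0:
        raise ValueError("thresholds must lie in [0, 100]")
    strain_id = proteome.strain_id if isinstance(proteome, StrainProteome) else "?"
    proteins = list(proteome)
    cov_floor = 100.0 if exact_coverage else min_query_coverage_pct

    hits: list[MarkerHit] = []
    if not proteins:
        logger.warning("screen: empty proteome for %s; all markers absent", strain_id)
        hits = [MarkerHit(m.marker_id, m.category, present=False) for m in panel]
        return ScreenResult(strain_id, hits, min_identity_pct, cov_floor)

    for marker in panel:
        best = None
        for protein in proteins:
            res = align_pair(
                ProteinRecord(marker.marker_id, "panel", marker.sequence),
                protein,
                params,
            )
            if best is None or res.score > best[0].score or (
                res.score == best[0].score and protein.protein_id < best[1]
            ):
                best = (res, protein.protein_id)
        res, pid = best
        present = (
            res.identity_pct > min_identity_pct
            and res.query_coverage_pct >= cov_floor - 1e-9
        )
        if present:
            hits.append(
                MarkerHit(
                    marker.marker_id,
                    marker.category,
                    present=True,
                    best_hit=pid,
                    identity_pct=res.identity_pct,
                    query_coverage_pct=res.query_coverage_pct,
                )
            )
        else:
            hits.append(MarkerHit(marker.marker_id, marker.category, present=False))
    return ScreenResult(strain_id, hits, min_identity_pct, cov_floor)
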