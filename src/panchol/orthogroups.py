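"""Orthogroup inference from a hit table: reciprocal best hits plus clustering.

A reciprocal best hit (RBH) is a cross-strain protein pair in which each
protein is the other's highest-scoring match within the partner strain — the
standard orthology proxy. Orthogroups are connected components of the RBH
graph; a within-strain paralog left unassigned (for example, the second copy
of a duplicated gene) is attached to a component when its score to a
same-strain member reaches that member's weakest cross-strain RBH score.
Remaining proteins become singleton orthogroups.

The presence/absence matrix over (orthogroup, strain) with per-cell copy
numbers is the substrate for the core/accessory/unique partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .align import AlignParams, HitTable, align_pair, kmer_sets
from .io import ProteinRecord, StrainProteome, logger


@dataclass
class Orthogroup:
    """One inferred gene family: member proteins and the strains they span."""

    orthogroup_id: str
    members: list[ProteinRecord]
    cog_class: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"orthogroup {self.orthogroup_id}: empty member set")

    @property
    def strains_present(self) -> frozenset[str]:
        return frozenset(m.strain_id for m in self.members)

    def copy_number(self, strain_id: str) -> int:
        return sum(1 for m in self.members if m.strain_id == strain_id)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PresenceAbsenceMatrix:
    """Copy-number matrix: rows = orthogroups, columns = strains.

    ``counts`` holds per-cell member counts (0 = absent); ``presence`` is the
    boolean view. Every row has at least one present cell.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.sum(axis=1) == 0).any():
            empty = self.counts.index[self.counts.sum(axis=1) == 0][0]
            raise ValueError(f"orthogroup {empty!r} has no present strain")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("copy numbers must be non-negative")

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    @property
    def strain_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.counts.index)

    def __len__(self) -> int:
        return len(self.counts)


def _tie_break_frame(group: pd.DataFrame) -> pd.Series:
    """Pick the best hit row: max score, then higher identity, then lexicographic id."""
    best_score = group["score"].max()
    tied = group[group["score"] == best_score]
    if len(tied) > 1:
        ident = tied["identity_pct"].fillna(-1.0)
        tied = tied[ident == ident.max()]
    return tied.sort_values("other_id").iloc[0]


def reciprocal_best_hits(
    hits: HitTable,
    min_identity_pct: float = 30.0,
    min_coverage_pct: float = 50.0,
    proteins: Optional[dict[str, ProteinRecord]] = None,
) -> list[tuple[str, str]]:
    """Extract the RBH edge list from a hit table.

    An edge (p, q) is emitted iff q is p's highest-scoring hit among q's strain
    AND p is q's highest-scoring hit among p's strain, with ties broken by
    higher identity then lexicographically smaller partner id. Edges must also
    reach the minimum identity/coverage quality gate (guards against spurious
    single-domain links); when the table lacks identity statistics for a
    candidate edge they are recomputed from ``proteins``.

    Returns sorted (p, q) tuples with p < q; the edge set is symmetric by
    construction.
    """
    df = hits.hits
    if df.empty:
        return []
    # view every stored pair from both ends
    fwd = df.rename(columns={"query_id": "self_id", "subject_id": "other_id",
                             "subject_strain": "other_strain", "qcov_pct": "self_cov"})
    rev = df.rename(columns={"subject_id": "self_id", "query_id": "other_id",
                             "query_strain": "other_strain", "scov_pct": "self_cov"})
    both = pd.concat(
        [fwd[["self_id", "other_id", "other_strain", "score", "identity_pct", "self_cov"]],
         rev[["self_id", "other_id", "other_strain", "score", "identity_pct", "self_cov"]]],
        ignore_index=True,
    )
    best: dict[tuple[str, str], str] = {}
    quality: dict[tuple[str, str], tuple[float, float]] = {}
    for (self_id, other_strain), group in both.groupby(
        ["self_id", "other_strain"], sort=False
    ):
        row = _tie_break_frame(group)
        best[(self_id, other_strain)] = row["other_id"]
        quality[(self_id, row["other_id"])] = (row["identity_pct"], row["self_cov"])

    strain_of = {}
    for col_self, col_strain in (("query_id", "query_strain"), ("subject_id", "subject_strain")):
        strain_of.update(dict(zip(df[col_self], df[col_strain])))

    edges: set[tuple[str, str]] = set()
    for (p, other_strain), q in best.items():
        if best.get((q, strain_of[p])) != p:
            continue
        pair = (p, q) if p < q else (q, p)
        if pair in edges:
            continue
        identity, cov = quality.get((p, q), (np.nan, np.nan))
        identity2, cov2 = quality.get((q, p), (np.nan, np.nan))
        identity = np.nanmax([identity, identity2])
        cov = np.nanmin([cov, cov2])
        if np.isnan(identity):
            if proteins is None:
                raise ValueError(
                    f"edge ({p}, {q}) lacks identity statistics; pass `proteins` "
                    "to recompute or build the hit table with stats='full'"
                )
            res = align_pair(proteins[p], proteins[q], hits.params)
            identity = res.identity_pct
            cov = min(res.query_coverage_pct, res.subject_coverage_pct)
        if identity >= min_identity_pct and (np.isnan(cov) or cov >= min_coverage_pct):
            edges.add(pair)
    return sorted(edges)


def build_orthogroups(
    rbh_edges: Sequence[tuple[str, str]],
    hits: HitTable,
    proteomes: Sequence[StrainProteome],
    params: Optional[AlignParams] = None,
    prefilter_k: int = 4,
    paralog_score_fraction: float = 0.9,
    min_identity_pct: float = 30.0,
    min_coverage_pct: float = 50.0,
) -> list[Orthogroup]:
    """Cluster proteins into orthogroups.

    Connected components of the RBH graph, then the paralog-attachment pass:
    an unassigned protein joins a component when its alignment score to any
    member (shared-kmer gated) reaches ``paralog_score_fraction`` of that
    member's weakest cross-strain RBH score (ties resolved toward the highest
    such score, then the smaller component id). The fractional slack (default
    0.9) absorbs the mutation-load variance of duplicated copies: a copy
    slightly more diverged than every true member would otherwise lose to
    every member's weakest edge simultaneously, while scores to non-homologous
    proteins sit an order of magnitude lower, so the slack costs no
    specificity.

    A final pass groups still-unassigned within-strain duplicates: a gene
    family private to one strain that carries two copies produces no
    cross-strain hit at all, so neither RBH components nor attachment can see
    it; such pairs are joined when they pass the same identity/coverage gate
    as RBH edges. Everything still unassigned becomes a singleton.

    Orthogroup ids are OG0000001... assigned by sorted smallest member id, so
    identical inputs give identical ids. The consensus COG class is the modal
    member class (ties -> lexicographically smallest; all-unannotated -> None).
    """
    params = params or hits.params
    proteins: dict[str, ProteinRecord] = {}
    for prot in proteomes:
        for p in prot:
            if p.protein_id in proteins:
                raise ValueError(f"protein id {p.protein_id!r} occurs in two strains")
            proteins[p.protein_id] = p
    for p, q in rbh_edges:
        if p not in proteins or q not in proteins:
            raise ValueError(f"RBH edge references unknown protein {p!r} or {q!r}")

    graph = nx.Graph()
    graph.add_nodes_from(proteins)
    graph.add_edges_from(rbh_edges)
    components = [sorted(c) for c in nx.connected_components(graph) if len(c) > 1]
    components.sort(key=lambda c: c[0])

    # weakest cross-strain RBH score per member protein
    edge_scores: dict[tuple[str, str], float] = {}
    df = hits.hits
    lookup = {(a, b): s for a, b, s in zip(df["query_id"], df["subject_id"], df["score"])}
    for p, q in rbh_edges:
        s = lookup.get((p, q), lookup.get((q, p)))
        if s is None:
            res = align_pair(proteins[p], proteins[q], params)
            s = res.score
        edge_scores[(p, q)] = edge_scores[(q, p)] = s
    weakest: dict[str, float] = {}
    for (p, q), s in edge_scores.items():
        weakest[p] = min(weakest.get(p, np.inf), s)

    assigned = {pid for comp in components for pid in comp}
    unassigned = sorted(set(proteins) - assigned)

    # paralog attachment: any member qualifies; candidate (paralog, member)
    # pairs are gated by a >=5 shared-4-mer check so only plausibly homologous
    # pairs are aligned (random same-length pairs share ~0-2 4-mers)
    kmers = {pid: next(iter(kmer_sets([proteins[pid].sequence], prefilter_k)))
             for pid in proteins}
    attached: dict[int, list[str]] = {}
    for pid in unassigned:
        best_choice: Optional[tuple[float, int]] = None  # (-score, comp_idx)
        for ci, comp in enumerate(components):
            for member in comp:
                if len(kmers[pid] & kmers[member]) < 5:
                    continue
                score = align_pair(proteins[pid], proteins[member], params).score
                if score >= paralog_score_fraction * weakest.get(member, np.inf):
                    cand = (-score, ci)
                    if best_choice is None or cand < best_choice:
                        best_choice = cand
        if best_choice is not None:
            attached.setdefault(best_choice[1], []).append(pid)

    final_members: list[list[str]] = []
    for ci, comp in enumerate(components):
        final_members.append(sorted(comp + attached.get(ci, [])))
    claimed = {pid for comp in final_members for pid in comp}

    # within-strain duplicate grouping over the leftovers
    leftovers = sorted(set(proteins) - claimed)
    dup_graph = nx.Graph()
    dup_graph.add_nodes_from(leftovers)
    by_strain: dict[str, list[str]] = {}
    for pid in leftovers:
        by_strain.setdefault(proteins[pid].strain_id, []).append(pid)
    for strain, pids in sorted(by_strain.items()):
        for i, p in enumerate(pids):
            for q in pids[i + 1 :]:
                if len(kmers[p] & kmers[q]) < 5:
                    continue
                res = align_pair(proteins[p], proteins[q], params)
                cov = min(res.query_coverage_pct, res.subject_coverage_pct)
                if res.identity_pct >= min_identity_pct and cov >= min_coverage_pct:
                    dup_graph.add_edge(p, q)
    final_members.extend(sorted(c) for c in nx.connected_components(dup_graph))
    final_members.sort(key=lambda c: c[0])

    groups: list[Orthogroup] = []
    for idx, member_ids in enumerate(final_members, start=1):
        members = [proteins[pid] for pid in member_ids]
        groups.append(
            Orthogroup(
                orthogroup_id=f"OG{idx:07d}",
                members=members,
                cog_class=consensus_cog(members),
            )
        )
    total = sum(len(g) for g in groups)
    if total != len(proteins):
        raise AssertionError("orthogroups do not partition the protein set")
    logger.info("build_orthogroups: %d proteins -> %d orthogroups", total, len(groups))
    return groups


def consensus_cog(members: Sequence[ProteinRecord]) -> Optional[str]:
    """Modal member COG class; ties -> lexicographically smallest; none -> None."""
    classes = [m.cog_class for m in members if m.cog_class]
    if not classes:
        return None
    counts = pd.Series(classes).value_counts()
    top = counts[counts == counts.max()]
    return sorted(top.index)[0]


def presence_matrix(
    orthogroups: Sequence[Orthogroup], strain_ids: Sequence[str]
) -> PresenceAbsenceMatrix:
    """Copy-number matrix over (orthogroup, strain); cell = member count."""
    strain_ids = list(strain_ids)
    known = set(strain_ids)
    data = np.zeros((len(orthogroups), len(strain_ids)), dtype=np.int64)
    col = {s: i for i, s in enumerate(strain_ids)}
    for r, og in enumerate(orthogroups):
        for m in og.members:
            if m.strain_id not in known:
                raise ValueError(
                    f"orthogroup {og.orthogroup_id} contains strain "
                    f"{m.strain_id!r} not in strain_ids"
                )
            data[r, col[m.strain_id]] += 1
    counts = pd.DataFrame(
        data, index=[og.orthogroup_id for og in orthogroups], columns=strain_ids
    )
    return PresenceAbsenceMatrix(counts=counts)


def orthogroups_to_frame(orthogroups: Sequence[Orthogroup]) -> pd.DataFrame:
    """Long-form table: orthogroup_id, protein_id, strain_id, cog_class."""
    rows = [
        (og.orthogroup_id, m.protein_id, m.strain_id, og.cog_class or "")
        for og in orthogroups
        for m in og.members
    ]
    return pd.DataFrame(
        rows, columns=["orthogroup_id", "protein_id", "strain_id", "cog_class"]
    )


def infer_orthogroups(
    proteomes: Sequence[StrainProteome],
    params: AlignParams = AlignParams(),
    min_rbh_identity_pct: float = 30.0,
    min_rbh_coverage_pct: float = 50.0,
    prefilter_k: int = 4,
    prefilter_min_shared: int = 1,
    stats: str = "best",
    paralog_score_fraction: float = 0.9,
) -> tuple[list[Orthogroup], PresenceAbsenceMatrix, HitTable]:
    """Convenience pipeline: all-vs-all -> RBH -> orthogroups -> matrix."""
    from .align import all_vs_all

    hits = all_vs_all(
        proteomes,
        params,
        prefilter_k=prefilter_k,
        prefilter_min_shared=prefilter_min_shared,
        stats=stats,  # type: ignore[arg-type]
    )
    proteins = {p.protein_id: p for prot in proteomes for p in prot}
    edges = reciprocal_best_hits(
        hits,
        min_identity_pct=min_rbh_identity_pct,
        min_coverage_pct=min_rbh_coverage_pct,
        proteins=proteins,
    )
    groups = build_orthogroups(edges, hits, proteomes, params, prefilter_k=prefilter_k,
                               paralog_score_fraction=paralog_score_fraction,
                               min_identity_pct=min_rbh_identity_pct,
                               min_coverage_pct=min_rbh_coverage_pct)
    matrix = presence_matrix(groups, [p.strain_id for p in proteomes])
    return groups, matrix, hits
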