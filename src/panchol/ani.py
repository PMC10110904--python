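"""Fragment-based average nucleotide identity, divergence, and NJ dendrograms.

ANI between two genomes is estimated Goris-style: the query genome is cut into
non-overlapping fragments (default 1,000 bp; the terminal remainder is
discarded; fragments with more than 10% N are skipped), each fragment is
aligned semi-globally against the subject genome, and fragments reaching the
minimum identity (default 70%) are retained; the one-way ANI is their mean
identity and the reported ANI is the mean of the two directions, which makes
the matrix exactly symmetric. Fragment identity is edit-distance based:
``100 * (1 - edit_distance / fragment_length)`` from edlib's semi-global
("HW") alignment, which always consumes the whole fragment, so fragment
coverage is complete by construction.

Divergence is ``100 - ANI`` (percent scale); a divergence matrix feeds the
Saitou-Nei neighbor-joining algorithm to build the strain dendrogram, written
as Newick with branch lengths.

~95-96% ANI approximates the bacterial species boundary; two unrelated random
sequences sit near 25% identity, far below the 70% fragment floor, and yield
an undefined (NaN) ANI rather than a misleading number.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .io import logger


@dataclass
class GenomeSequence:
    """A strain's nucleotide genome as a list of contigs (ACGT plus N)."""

    strain_id: str
    contigs: list[str]

    def __post_init__(self) -> None:
        if not self.contigs or all(len(c) == 0 for c in self.contigs):
            raise ValueError(f"genome {self.strain_id!r} is empty")

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass(frozen=True)
class AniParams:
    fragment_length: int = 1000
    min_fragment_identity_pct: float = 70.0
    min_fragment_coverage_pct: float = 70.0
    max_n_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.fragment_length < 100:
            raise ValueError("fragment_length must be >= 100 bp")
        if not 0.0 <= self.min_fragment_identity_pct <= 100.0:
            raise ValueError("min_fragment_identity_pct must lie in [0, 100]")


def genome_fragments(genome: GenomeSequence, params: AniParams) -> list[str]:
    """Non-overlapping fragments; terminal remainders and N-rich windows dropped."""
    frags: list[str] = []
    L = params.fragment_length
    for contig in genome.contigs:
        for start in range(0, len(contig) - L + 1, L):
            frag = contig[start : start + L]
            if frag.count("N") / L > params.max_n_fraction:
                continue
            frags.append(frag)
    return frags


def _one_way_ani(a: GenomeSequence, b: GenomeSequence, params: AniParams) -> float:
    """Mean identity of a's retained fragments against b, or NaN if none."""
    L = params.fragment_length
    max_dist = int(math.floor(L * (1.0 - params.min_fragment_identity_pct / 100.0)))
    identities: list[float] = []
    for frag in genome_fragments(a, params):
        best = -1
        for contig in b.contigs:
            res = edlib.align(frag, contig, mode="HW", task="distance", k=max_dist)
            d = res["editDistance"]
            if d != -1 and (best == -1 or d < best):
                best = d
        if best != -1:
            identities.append(100.0 * (1.0 - best / L))
    if not identities:
        return math.nan
    return float(np.mean(identities))


def ani(a: GenomeSequence, b: GenomeSequence, params: AniParams = AniParams()) -> float:
    """Bidirectionally averaged fragment ANI between two genomes, in percent.

    Returns NaN (with a warning) when either direction retains no fragment —
    the genomes are too diverged for a meaningful fragment-level estimate.
    """
    for g in (a, b):
        if g.length < 10 * params.fragment_length:
            logger.warning(
                "genome %s is shorter than 10 fragment lengths (%d bp); "
                "ANI estimate will be noisy",
                g.strain_id,
                g.length,
            )
    fwd = _one_way_ani(a, b, params)
    rev = _one_way_ani(b, a, params)
    if math.isnan(fwd) or math.isnan(rev):
        logger.warning(
            "ANI undefined for (%s, %s): no fragment passed the %g%% identity floor",
            a.strain_id,
            b.strain_id,
            params.min_fragment_identity_pct,
        )
        return math.nan
    return (fwd + rev) / 2.0


@dataclass
class DistanceMatrix:
    """Symmetric ANI matrix over strains; divergence = 100 - ANI."""

    ani: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.ani
        if list(m.index) != list(m.columns):
            raise ValueError("ANI matrix must have identical row/column strain ids")
        vals = m.to_numpy(dtype=float)
        if not np.allclose(np.diag(vals), 100.0):
            raise ValueError("ANI diagonal must be 100")
        finite = np.isfinite(vals)
        if not np.allclose(
            np.where(finite, vals, 0.0), np.where(finite.T, vals.T, 0.0), atol=0.5
        ):
            raise ValueError("ANI matrix asymmetric beyond 0.5 points")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.ani.index)

    @property
    def divergence(self) -> pd.DataFrame:
        div = 100.0 - self.ani
        np.fill_diagonal(div.values, 0.0)
        return div


def ani_matrix(
    genomes: Sequence[GenomeSequence], params: AniParams = AniParams()
) -> DistanceMatrix:
    """All-pairs bidirectional ANI over a genome set."""
    ids = [g.strain_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids in genome list")
    n = len(genomes)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = ani(genomes[i], genomes[j], params)
    return DistanceMatrix(ani=pd.DataFrame(m, index=ids, columns=ids))


def divergence_matrix(ani_values: DistanceMatrix | pd.DataFrame) -> pd.DataFrame:
    """100 - ANI, zero diagonal. Raises when any pair's ANI is undefined."""
    dm = ani_values if isinstance(ani_values, DistanceMatrix) else DistanceMatrix(ani_values)
    if np.isnan(dm.ani.to_numpy()).any():
        raise ValueError(
            "divergence undefined: some strain pairs have undefined (NaN) ANI; "
            "drop those strains or relax the fragment identity floor"
        )
    return dm.divergence


# --- neighbor joining ---------------------------------------------------------


@dataclass
class PhyloNode:
    """Tree node: leaves carry a name, internal nodes carry children.

    ``children`` is a list of (child, branch_length) pairs; branch lengths are
    in the distance matrix's units (divergence percentage points).
    """

    name: Optional[str] = None
    children: list[tuple["PhyloNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["PhyloNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child, _ in self.children for leaf in child.leaves()]


@dataclass
class PhyloTree:
    """Unrooted tree (rooted representation at the final NJ join)."""

    root: PhyloNode

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def leaf_distances(self) -> pd.DataFrame:
        """Patristic (path-length) distances between all leaf pairs."""
        # distances from every node to each leaf below it, merged upward
        names = self.leaf_names
        idx = {n: i for i, n in enumerate(names)}
        out = np.zeros((len(names), len(names)))

        def walk(node: PhyloNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: list[dict[str, float]] = []
            for child, length in node.children:
                sub = walk(child)
                below.append({k: v + length for k, v in sub.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for la, da in below[i].items():
                        for lb, db in below[j].items():
                            out[idx[la], idx[lb]] = out[idx[lb], idx[la]] = da + db
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self.root)
        return pd.DataFrame(out, index=names, columns=names)


def neighbor_joining(d: pd.DataFrame | DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Iteratively joins the pair minimizing the Q criterion
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``; branch lengths come from the
    standard two-point formulas. Ties are broken toward the lexicographically
    smallest (sorted) label pair, so output is deterministic. Negative branch
    lengths are clamped to zero with the deficit moved to the sibling branch
    (logged). With two leaves the single edge is split evenly.
    """
    if isinstance(d, DistanceMatrix):
        d = d.divergence
    if list(d.index) != list(d.columns):
        raise ValueError("distance matrix must have identical row/column labels")
    vals = d.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(vals), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")

    nodes: dict[str, PhyloNode] = {name: PhyloNode(name=name) for name in d.index}
    if len(nodes) == 1:
        return PhyloTree(root=next(iter(nodes.values())))
    dist: dict[tuple[str, str], float] = {}
    labels = list(d.index)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                dist[(a, b)] = dist[(b, a)] = float(vals[i, j])

    if len(labels) == 2:
        a, b = sorted(labels)
        half = dist[(a, b)] / 2.0
        root = PhyloNode(children=[(nodes[a], half), (nodes[b], half)])
        return PhyloTree(root=root)

    def clamp(x: float, sibling: float, pair: tuple[str, str]) -> tuple[float, float]:
        if x < 0.0:
            logger.info("NJ: clamping negative branch %.4g at join %s", x, pair)
            return 0.0, sibling + x if sibling + x > 0 else 0.0
        return x, sibling

    active = sorted(labels)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist[(a, b)] for b in active if b != a) for a in active}
        best_pair = None
        best_q = math.inf
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * dist[(a, b)] - r[a] - r[b]
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best_pair is None or (a, b) < best_pair)
                ):
                    best_q = q
                    best_pair = (a, b)
        a, b = best_pair
        dab = dist[(a, b)]
        limb_a = dab / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        limb_b = dab - limb_a
        limb_a, limb_b = clamp(limb_a, limb_b, (a, b))
        limb_b, limb_a = clamp(limb_b, limb_a, (a, b))
        counter += 1
        new_label = f"@internal{counter}"
        nodes[new_label] = PhyloNode(
            children=[(nodes[a], limb_a), (nodes[b], limb_b)]
        )
        for c in active:
            if c in (a, b):
                continue
            duc = (dist[(a, c)] + dist[(b, c)] - dab) / 2.0
            dist[(new_label, c)] = dist[(c, new_label)] = duc
        active = sorted([c for c in active if c not in (a, b)] + [new_label])

    a, b, c = active
    dab, dac, dbc = dist[(a, b)], dist[(a, c)], dist[(b, c)]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    la = max(la, 0.0)
    lb = max(lb, 0.0)
    lc = max(lc, 0.0)
    root = PhyloNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root=root)


_NEEDS_QUOTE = re.compile(r"[\s()\[\]'\":;,]")


def _format_label(name: str) -> str:
    if _NEEDS_QUOTE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: PhyloTree, decimals: int = 6) -> str:
    """Standard Newick with branch lengths; labels with spaces are quoted."""

    def render(node: PhyloNode) -> str:
        if node.is_leaf:
            return _format_label(node.name or "")
        inner = ",".join(
            f"{render(child)}:{length:.{decimals}f}" for child, length in node.children
        )
        return f"({inner})"

    return render(tree.root) + ";"


def write_newick(tree: PhyloTree, path, decimals: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, decimals=decimals) + "\n")
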