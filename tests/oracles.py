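"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: the affine-gap aligner is a
plain O(nm) dynamic programme over explicit H/E/F state matrices, the best-hit
scan follows the reciprocal-best-hit definition literally, and additive
distance matrices are derived by summing branch lengths on explicitly
constructed random trees.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

NEG = -1e9


def dp_score(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    mode: str = "local",
) -> float:
    """Optimal alignment score; a gap of length k costs gap_open + k*gap_extend."""
    M = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    local = mode == "local"
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        H[0, j] = 0.0 if local else -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        H[i, 0] = 0.0 if local else -(gap_open + gap_extend * i)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = M[a[i - 1], b[j - 1]]
            E[i, j] = max(H[i, j - 1] - gap_open - gap_extend, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_extend, F[i - 1, j] - gap_extend)
            h = max(H[i - 1, j - 1], E[i - 1, j - 1], F[i - 1, j - 1]) + s
            cand = max(h, E[i, j], F[i, j])
            if local:
                cand = max(cand, 0.0)
            H[i, j] = cand
            best = max(best, cand)
    if local:
        return float(best)
    return float(max(H[n, m], E[n, m], F[n, m]))


def best_hit_scan(score: dict[tuple[str, str], float], strain_of: dict[str, str]):
    """RBH edges straight from the definition.

    ``score`` maps unordered protein pairs (both orders present) to alignment
    scores; returns the set of sorted (p, q) pairs where each protein is the
    other's highest-scoring partner within the partner's strain. Ties broken
    by lexicographically smaller partner id (matching the documented policy
    when identities are equal).
    """
    proteins = sorted(strain_of)
    edges = set()
    def best_in(p: str, strain: str):
        cands = [
            (q, s) for (x, q), s in score.items()
            if x == p and strain_of[q] == strain
        ]
        if not cands:
            return None
        top = max(s for _, s in cands)
        return sorted(q for q, s in cands if s == top)[0]

    for p in proteins:
        for strain in sorted(set(strain_of.values())):
            if strain == strain_of[p]:
                continue
            q = best_in(p, strain)
            if q is None:
                continue
            if best_in(q, strain_of[p]) == p:
                edges.add(tuple(sorted((p, q))))
    return edges


def random_additive_matrix(n_taxa: int, rng: np.random.Generator):
    """(labels, matrix, newick) for a random binary tree with positive branches.

    The matrix of leaf-to-leaf path lengths is additive by construction, so a
    correct neighbor-joining implementation must reproduce it exactly.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # start from 3-star, insert remaining leaves on random edges
    nodes = {"root": []}
    import itertools

    class N:
        __slots__ = ("name", "children")
        def __init__(self, name=None):
            self.name = name
            self.children = []  # (child, length)

    root = N()
    edges = []
    for leaf in labels[:3]:
        child = N(leaf)
        length = float(rng.uniform(0.5, 3.0))
        root.children.append([child, length])
        edges.append((root, root.children[-1]))
    for leaf in labels[3:]:
        parent, slot = edges[rng.integers(len(edges))]
        child, length = slot
        split = float(rng.uniform(0.2, 0.8)) * length
        mid = N()
        slot[0] = mid
        slot[1] = split
        mid.children.append([child, length - split])
        new = N(leaf)
        mid.children.append([new, float(rng.uniform(0.5, 3.0))])
        edges.append((mid, mid.children[0]))
        edges.append((mid, mid.children[1]))

    # leaf-to-leaf distances by recursive merge
    dist = np.zeros((n_taxa, n_taxa))
    idx = {name: i for i, name in enumerate(labels)}

    def walk(node):
        if node.name is not None:
            return {node.name: 0.0}
        groups = []
        for child, length in node.children:
            sub = walk(child)
            groups.append({k: v + length for k, v in sub.items()})
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for la, da in groups[i].items():
                    for lb, db in groups[j].items():
                        dist[idx[la], idx[lb]] = dist[idx[lb], idx[la]] = da + db
        merged = {}
        for g in groups:
            merged.update(g)
        return merged

    def newick(node):
        if node.name is not None:
            return node.name
        inner = ",".join(f"{newick(c)}:{l:.6f}" for c, l in node.children)
        return f"({inner})"

    walk(root)
    return labels, dist, newick(root) + ";"
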