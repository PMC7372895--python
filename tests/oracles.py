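"""Independent reference implementations used to validate the package.

Everything here is deliberately naive: full-matrix dynamic programming with
no seeding, banding or windowing; per-base occupancy counting; exhaustive
greedy clustering.  These are the oracles the fast implementations are
checked against, so they must not share code with the package internals.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=True)
def sw_full(q, s, match, mismatch, gap_open, gap_extend):
    """Full-matrix affine-gap local alignment.

    Returns (score, q_start, q_end, s_start, s_end, n_match, n_cols).
    Stores complete H/E/F matrices and traces back by value comparison.
    Gap of length L costs gap_open + L * gap_extend; N (code 4) never
    matches.
    """
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    go_ge = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - go_ge
            if E[i, j - 1] - gap_extend > e:
                e = E[i, j - 1] - gap_extend
            E[i, j] = e
            f = H[i - 1, j] - go_ge
            if F[i - 1, j] - gap_extend > f:
                f = F[i - 1, j] - gap_extend
            F[i, j] = f
            if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] - mismatch
            h = 0
            if diag > h:
                h = diag
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    # value-based traceback (prefer stop, then diag, then E, then F)
    i, j = bi, bj
    state = 0
    n_match = 0
    n_cols = 0
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] - mismatch
            if H[i, j] == diag:
                n_cols += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    n_match += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            n_cols += 1
            if E[i, j] == H[i, j - 1] - go_ge:
                j -= 1
                state = 0
            else:
                j -= 1
        else:
            n_cols += 1
            if F[i, j] == H[i - 1, j] - go_ge:
                i -= 1
                state = 0
            else:
                i -= 1
    return best, i, bi, j, bj, n_match, n_cols


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode_oracle(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.uint8)


def coverage_by_occupancy(intervals, gene_length: int) -> float:
    """Per-base occupancy count over [0, gene_length)."""
    occupied = np.zeros(gene_length, dtype=bool)
    for start, end in intervals:
        occupied[max(start, 0) : min(end, gene_length)] = True
    return float(occupied.sum()) / gene_length


def greedy_cluster_oracle(
    genes,
    identity_threshold: float = 0.90,
    coverage_threshold: float = 0.80,
    match: int = 1,
    mismatch: int = 2,
    gap_open: int = 5,
    gap_extend: int = 2,
):
    """Exhaustive greedy longest-first clustering with full-DP decisions.

    ``genes`` are GeneRecord-like objects with .sequence/.genome_id/.gene_id.
    Returns a list of clusters, each a list of gene objects (first element
    is the representative).
    """
    ordered = sorted(
        genes, key=lambda g: (-len(g.sequence), g.genome_id, g.gene_id)
    )
    clusters: list[list] = []
    for gene in ordered:
        q = encode_oracle(gene.sequence)
        placed = False
        for cluster in clusters:
            rep = cluster[0]
            score, qs, qe, _ss, _se, n_match, n_cols = sw_full(
                q, encode_oracle(rep.sequence), match, mismatch, gap_open, gap_extend
            )
            if n_cols == 0:
                continue
            identity = n_match / n_cols
            coverage = (qe - qs) / len(gene.sequence)
            if identity >= identity_threshold and coverage >= coverage_threshold:
                cluster.append(gene)
                placed = True
                break
        if not placed:
            clusters.append([gene])
    return clusters


def random_additive_tree(rng, n_taxa: int):
    """A random binary tree with positive branch lengths plus its additive
    leaf-to-leaf distance matrix.

    Returns (newick string, labels, distance matrix).
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # grow by sequential attachment; represent as an explicit graph
    import itertools

    next_internal = [n_taxa]
    edges: dict[tuple[int, int], float] = {}

    def add_edge(a, b, w):
        edges[(min(a, b), max(a, b))] = w

    def blen():
        return float(rng.uniform(0.05, 1.0))

    # start with a 3-star
    center = next_internal[0]
    next_internal[0] += 1
    for leaf in range(3):
        add_edge(leaf, center, blen())
    for leaf in range(3, n_taxa):
        # split a random existing edge and hang the new leaf off it
        key = tuple(sorted(edges))[int(rng.integers(0, len(edges)))]
        w = edges.pop(key)
        mid = next_internal[0]
        next_internal[0] += 1
        t = float(rng.uniform(0.2, 0.8))
        add_edge(key[0], mid, w * t)
        add_edge(key[1], mid, w * (1 - t))
        add_edge(leaf, mid, blen())

    # path distances by BFS over the tree
    adj: dict[int, list[tuple[int, float]]] = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    n_nodes = next_internal[0]
    dist = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        d = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in d:
                    d[v] = d[u] + w
                    stack.append(v)
        for dst in range(n_taxa):
            dist[src, dst] = d[dst]

    # newick via rooting at the first internal node
    def to_newick(node, parent):
        kids = [(v, w) for v, w in adj[node] if v != parent]
        if not kids:
            return labels[node]
        inner = ",".join(f"{to_newick(v, node)}:{w:.6f}" for v, w in kids)
        return f"({inner})"

    newick = to_newick(n_taxa, None) + ";"
    return newick, labels, dist
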