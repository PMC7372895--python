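"""Gene-content phylogeny: distances from the presence-absence matrix and
neighbor-joining tree construction with Newick output.

Neighbor joining is implemented with deterministic tie-breaking (first
minimal pair in label order).  Negative branch lengths are clamped to zero
and the deficit is transferred to the sister branch, preserving the
pairwise sum.  A two-state symmetric-model (CFN/Mk2) log-likelihood of a
fixed topology is provided so a binary-character ML criterion can be
scored, though no topology search is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write(f"{len(self.labels)}\n")
            for i, label in enumerate(self.labels):
                row = "\t".join(f"{v:.6f}" for v in self.values[i])
                out.write(f"{label}\t{row}\n")


@dataclass
class TreeNode:
    """Node of an (implicitly unrooted) tree; root is the NJ center."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out: list[TreeNode] = []
        for child, _bl in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if not self.children:
            return self.name or ""
        parts = [
            f"{child._newick_inner()}:{bl:.6f}" for child, bl in self.children
        ]
        label = self.name or ""
        return f"({','.join(parts)}){label}"


def gene_content_distance(matrix, metric: str = "jaccard") -> DistanceMatrix:
    """Pairwise genome distances from a presence-absence matrix.

    jaccard: 1 - |shared present genes| / |union of present genes| (two
    genomes with no present genes at all are defined as distance 0).
    hamming: fraction of disagreeing cells.
    """
    cells = np.asarray(matrix.cells, dtype=bool)
    labels = list(matrix.genome_order)
    n = len(labels)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = cells[:, i], cells[:, j]
            if metric == "jaccard":
                union = int(np.logical_or(a, b).sum())
                if union == 0:
                    logger.warning(
                        "genomes %s and %s share no present genes; "
                        "jaccard distance defined as 0", labels[i], labels[j]
                    )
                    dist = 0.0
                else:
                    inter = int(np.logical_and(a, b).sum())
                    dist = 1.0 - inter / union
            elif metric == "hamming":
                dist = float(np.mean(a != b)) if a.size else 0.0
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=labels, values=d)


def _clamped_pair(left: float, right: float) -> tuple[float, float]:
    """Clamp negatives to 0, moving the deficit to the sister branch."""
    if left < 0:
        right = max(right + left, 0.0)
        left = 0.0
    elif right < 0:
        left = max(left + right, 0.0)
        right = 0.0
    return left, right


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classic neighbor joining; requires at least 3 taxa."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    # validation of symmetry etc. happens in DistanceMatrix.__post_init__
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]
    d = dm.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        m = len(active)
        best = None
        best_q = math.inf
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        bl_i = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        bl_j = d[i, j] - bl_i
        bl_i, bl_j = _clamped_pair(bl_i, bl_j)
        parent = TreeNode(children=[(nodes[i], bl_i), (nodes[j], bl_j)])
        # grow the matrix with the new node's distances
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    bl_i = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    bl_j = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    bl_k = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    bl_i = max(bl_i, 0.0)
    bl_j = max(bl_j, 0.0)
    bl_k = max(bl_k, 0.0)
    return TreeNode(
        children=[(nodes[i], bl_i), (nodes[j], bl_j), (nodes[k], bl_k)]
    )


def write_newick(tree: TreeNode, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write(tree.newick() + "\n")


def cfn_log_likelihood(tree: TreeNode, matrix) -> float:
    """Log-likelihood of the binary matrix on a fixed tree under the
    two-state symmetric model (CFN/Mk2) via the pruning algorithm.

    Transition probability along a branch of length t:
    P(stay) = (1 + exp(-2t)) / 2, P(flip) = (1 - exp(-2t)) / 2, with
    stationary frequencies 1/2.  Branch lengths are taken as given.
    """
    cells = np.asarray(matrix.cells, dtype=int)
    col_of = {g: j for j, g in enumerate(matrix.genome_order)}

    def partials(node: TreeNode) -> np.ndarray:
        if not node.children:
            j = col_of[node.name]
            states = cells[:, j]
            out = np.zeros((cells.shape[0], 2))
            out[np.arange(cells.shape[0]), states] = 1.0
            return out
        result = np.ones((cells.shape[0], 2))
        for child, bl in node.children:
            child_p = partials(child)
            stay = (1.0 + math.exp(-2.0 * max(bl, 0.0))) / 2.0
            flip = 1.0 - stay
            trans = np.array([[stay, flip], [flip, stay]])
            result *= child_p @ trans.T
        return result

    root_p = partials(tree)
    site_lik = 0.5 * root_p.sum(axis=1)
    site_lik = np.clip(site_lik, 1e-300, None)
    return float(np.log(site_lik).sum())
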