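"""Hamming distances between region presence profiles and neighbor-joining trees.

Distances are raw counts of variant keys whose presence differs between two
regions (a metric on binary vectors; no per-site normalization).  An
all-absent "Normal" pseudo-sample can be appended as a germline reference
point, which makes the trunk branch length equal the truncal mutation count.

Neighbor joining is the classic agglomerative algorithm: the Q criterion

    Q(i, j) = (n − 2)·d(i, j) − r_i − r_j,    r_i = Σ_k d(i, k)

is minimized over pairs, the pair is joined with standard branch lengths

    L_i = d(i, j)/2 + (r_i − r_j) / (2(n − 2)),   L_j = d(i, j) − L_i,

and distances to the new node are d(u, k) = (d(i, k) + d(j, k) − d(i, j))/2.
Two details the algorithm leaves open are fixed deterministically: Q-ties
break on the lexicographically smallest label pair (a joined cluster carries
its smallest leaf label), and negative branch-length estimates are clamped
to 0.  Trees are scikit-bio ``TreeNode`` objects, serialized as Newick.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .clonality import PresenceMatrix

__all__ = [
    "DistanceMatrix",
    "ROOT_LABEL",
    "hamming_distance_matrix",
    "neighbor_joining",
    "to_newick",
    "read_newick",
]

ROOT_LABEL = "Normal"


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # (n, n) non-negative, zero diagonal, symmetric

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape disagrees with labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if (m < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("non-zero diagonal")
        self.matrix = m


def hamming_distance_matrix(
    matrix: PresenceMatrix, include_root: bool = True
) -> DistanceMatrix:
    """Pairwise Hamming distances between region presence rows.

    With ``include_root``, an all-zero germline pseudo-sample named
    ``Normal`` is appended; its distance to a region is that region's
    variant count.
    """
    cells = matrix.cells.astype(np.int64)
    labels = list(matrix.region_labels)
    if include_root:
        if ROOT_LABEL in labels:
            raise ValueError(f"region label clashes with root label {ROOT_LABEL!r}")
        cells = np.vstack([cells, np.zeros((1, cells.shape[1]), dtype=np.int64)])
        labels.append(ROOT_LABEL)
    n = len(labels)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = int((cells[i] != cells[j]).sum())
    return DistanceMatrix(labels=labels, matrix=d)


def _leaf(label: str, length: float | None = None) -> TreeNode:
    node = TreeNode(name=label)
    node.length = length
    return node


def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Build an unrooted NJ tree (returned with an arbitrary trifurcating or
    two-child root) from a distance matrix."""
    n = len(dist.labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    d = dist.matrix.astype(float).copy()
    nodes = [_leaf(lab) for lab in dist.labels]
    # each active cluster keeps its lexicographically smallest leaf label
    tie_labels = list(dist.labels)

    while len(nodes) > 2:
        m = len(nodes)
        r = d.sum(axis=1)
        best: tuple[float, tuple[str, str], tuple[int, int]] | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_labels = tuple(sorted((tie_labels[i], tie_labels[j])))
                cand = (q, pair_labels, (i, j))
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, (i, j) = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new cluster to the remaining ones
        keep = [k for k in range(m) if k not in (i, j)]
        new_row = np.array([(d[i, k] + d[j, k] - d[i, j]) / 2 for k in keep])
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        nodes = [nodes[k] for k in keep] + [parent]
        tie_labels = [tie_labels[k] for k in keep] + [
            min(tie_labels[i], tie_labels[j])
        ]

    # the last two clusters are joined by a single edge; for an unrooted tree
    # the split of that edge is arbitrary, so it sits on the first cluster
    a, b = nodes
    a.length = max(float(d[0, 1]), 0.0)
    b.length = 0.0
    return TreeNode(children=[a, b])


def to_newick(tree: TreeNode, path: str | os.PathLike) -> None:
    """Serialize a tree with branch lengths as Newick; re-parses isomorphic."""
    tree.write(str(path), format="newick")


def read_newick(path: str | os.PathLike) -> TreeNode:
    return TreeNode.read(str(path), format="newick", convert_underscores=False)
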