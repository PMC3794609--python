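"""Genome-wide tissue distance matrices and neighbor-joining trees.

Each tissue is summarized by its mean expression profile over samples
(median available as a flag); the distance between two tissues is the
correlation distance 1 - PCC of their profiles, in [0, 2].  An unrooted
tree is then built with the classic neighbor-joining algorithm of Saitou
& Nei: repeatedly join the pair minimizing the Q criterion

    Q(i, j) = (r - 2) d(i, j) - R_i - R_j,   R_i = sum_k d(i, k),

with the standard branch-length and matrix-reduction formulas.  Ties in Q
are broken by the lexicographically smallest label pair so the result is
deterministic.  NJ is consistent: on exactly additive distances the tree's
path lengths reproduce the input matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .coordination import pairwise_pcc
from .expression import ExpressionCompendium

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "tissue_distance_matrix",
    "neighbor_joining",
    "write_newick",
    "read_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric tissue-tissue distances (1 - PCC units)."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distance matrix entries must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def tissue_distance_matrix(c: ExpressionCompendium, aggregate: str = "mean") -> DistanceMatrix:
    """Pairwise 1 - PCC distances between per-tissue expression profiles.

    The profile of a tissue is the per-gene mean (or median) over its
    samples.  A constant profile has no defined correlation and is an
    error naming the tissue.
    """
    tissues = c.tissues
    if len(tissues) < 3:
        raise ValueError("need at least 3 tissues for a distance matrix")
    if aggregate not in {"mean", "median"}:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    profiles = {}
    for t in tissues:
        block = c.tissue_values(t)
        p = block.mean(axis=1) if aggregate == "mean" else block.median(axis=1)
        p = p.to_numpy()
        if np.ptp(p) == 0.0:
            raise ValueError(f"tissue {t!r} has a zero-variance profile")
        profiles[t] = p
    n = len(tissues)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = pairwise_pcc(profiles[tissues[i]], profiles[tissues[j]])
            d[i, j] = d[j, i] = 1.0 - r
    return DistanceMatrix(tissues, d)


def neighbor_joining(D: DistanceMatrix, clamp_negative: bool = False) -> TreeNode:
    """Build an unrooted tree from a distance matrix by neighbor joining.

    Returns a scikit-bio ``TreeNode`` whose root is the trifurcation left
    by the final join (the standard unrooted representation).  Branch
    lengths are reported as the NJ formulas give them; negative lengths
    trigger a warning and can be clamped to zero with ``clamp_negative``.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    active: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in D.labels}
    # canonical sort key per active node: smallest leaf label beneath it
    canon: dict[str, str] = {lab: lab for lab in D.labels}
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((D.labels[i], D.labels[j]))] = D.d[i, j]

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    def length(node: TreeNode, value: float) -> None:
        if value < 0:
            warnings.warn(f"negative NJ branch length {value:.4g}", stacklevel=3)
            if clamp_negative:
                value = 0.0
        node.length = float(value)

    next_id = 0
    while len(active) > 3:
        names = list(active)
        r = len(names)
        R = {a: sum(d(a, b) for b in names if b != a) for a in names}
        best = None
        for x in range(r):
            for y in range(x + 1, r):
                a, b = names[x], names[y]
                q = (r - 2) * d(a, b) - R[a] - R[b]
                key = tuple(sorted((canon[a], canon[b])))
                if best is None or (q, key) < (best[0], best[1]):
                    best = (q, key, a, b)
        _, _, a, b = best
        la = d(a, b) / 2.0 + (R[a] - R[b]) / (2.0 * (r - 2))
        lb = d(a, b) - la
        u = TreeNode()
        length(active[a], la)
        length(active[b], lb)
        u.append(active[a])
        u.append(active[b])
        uname = f"_nj{next_id}"
        next_id += 1
        for k in names:
            if k in (a, b):
                continue
            dist[frozenset((uname, k))] = (d(a, k) + d(b, k) - d(a, b)) / 2.0
        canon[uname] = min(canon[a], canon[b])
        del active[a], active[b]
        active[uname] = u

    (a, b, c) = sorted(active, key=lambda k: canon[k])
    la = (d(a, b) + d(a, c) - d(b, c)) / 2.0
    lb = (d(a, b) + d(b, c) - d(a, c)) / 2.0
    lc = (d(a, c) + d(b, c) - d(a, b)) / 2.0
    root = TreeNode()
    for node_name, lv in ((a, la), (b, lb), (c, lc)):
        length(active[node_name], lv)
        root.append(active[node_name])
    return root


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree to Newick with branch lengths.

    Labels follow the standard Newick dialect scikit-bio implements:
    spaces are encoded as unquoted underscores, and labels containing a
    literal underscore (or other special characters) are quoted.
    ``read_newick`` inverts the encoding, so round trips preserve labels.
    """
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
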