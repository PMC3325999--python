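"""Euclidean distances from the product-score matrix and distance trees.

Each query is a point in M-dimensional product-score space (one coordinate
per library profile); the distance between two queries is the ordinary
Euclidean norm of the difference of their score vectors.  Trees are built
from the resulting N x N matrix with neighbor joining (the default) or the
BioNJ variant; branch support comes from resampling profile columns of the
N x M matrix (bootstrap with replacement, or 80% delete-jackknife) and
recomputing the tree per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import ProductScoreMatrix
from .tree import Node, PhyloTree

__all__ = [
    "DistanceMatrix",
    "SupportTree",
    "euclidean_distances",
    "nj_tree",
    "bionj_tree",
    "resample_support",
    "TREE_BACKENDS",
]


@dataclass
class DistanceMatrix:
    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                row = "\t".join(repr(float(x)) for x in self.values[i])
                fh.write(f"{name}\t{row}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            ids = fh.readline().rstrip("\n").split("\t")[1:]
            values = np.array(
                [[float(x) for x in line.rstrip("\n").split("\t")[1:]]
                 for line in fh]
            )
        return cls(values, ids)

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square-format writer (names truncated/padded to 10)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.values[i])
                fh.write(f"{name[:10]:<10} {row}\n")


def euclidean_distances(matrix: ProductScoreMatrix) -> DistanceMatrix:
    """D(X, Y) = sqrt(sum_m (x_m - y_m)^2) over the M score coordinates."""
    v = matrix.values
    if v.shape[0] < 2:
        raise ValueError("need at least two queries")
    gram = v @ v.T
    sq = np.diag(gram)
    d2 = sq[:, None] + sq[None, :] - 2 * gram
    d = np.sqrt(np.clip(d2, 0.0, None))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(matrix.row_ids))


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------
def _nj_core(dist: np.ndarray, ids: list[str], bionj: bool) -> PhyloTree:
    n = dist.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dist.astype(float).copy()
    var = d.copy()  # BioNJ variance estimates (proportional to distances)
    nodes: list[Node] = [Node(label) for label in ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # ties: smallest (row, column) pair in current active order
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li = max(li, 0.0)
        lj = max(lj, 0.0)

        parent = Node()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent.add_child(child_i)
        parent.add_child(child_j)

        others = [k for k in active if k != i and k != j]
        if bionj and others:
            vij = var[i, j]
            if vij > 0:
                diff = sum(var[j, k] - var[i, k] for k in others)
                lam = 0.5 + diff / (2.0 * len(others) * vij)
                lam = min(max(lam, 0.0), 1.0)
            else:
                lam = 0.5
        else:
            lam = 0.5
        for k in others:
            new_d = lam * (d[i, k] - li) + (1 - lam) * (d[j, k] - lj)
            new_v = lam * var[i, k] + (1 - lam) * var[j, k] \
                - lam * (1 - lam) * var[i, j]
            d[i, k] = d[k, i] = max(new_d, 0.0)
            var[i, k] = var[k, i] = max(new_v, 0.0)
        nodes[i] = parent
        active.remove(j)

    # final three-way join
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = Node()
    for k, length in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = max(length, 0.0)
        root.add_child(nodes[k])
    return PhyloTree(root, rooted=False)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor joining (Q criterion, Studier-Keppler updates).

    Deterministic: Q ties resolve to the smallest (row, column) index pair
    in the current matrix order; negative branch estimates clamp to 0.
    """
    return _nj_core(dm.values, dm.ids, bionj=False)


def bionj_tree(dm: DistanceMatrix) -> PhyloTree:
    """BioNJ: neighbor joining with variance-weighted distance updates."""
    return _nj_core(dm.values, dm.ids, bionj=True)


TREE_BACKENDS = {"nj": nj_tree, "bionj": bionj_tree}


# ----------------------------------------------------------------------
# resampling support
# ----------------------------------------------------------------------
@dataclass
class SupportTree:
    """Point-estimate tree plus per-internal-branch support percentages."""

    tree: PhyloTree
    supports: dict[frozenset, float] = field(default_factory=dict)

    def annotate(self) -> PhyloTree:
        """Copy of the tree with supports written onto internal nodes."""
        out = self.tree.copy()
        labels = set(out.leaf_labels())
        ref = min(labels)
        n = len(labels)

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not out.root:
                side = below if ref not in below else labels - below
                if 2 <= len(side) <= n - 2:
                    node.support = self.supports.get(frozenset(side))
            return below

        walk(out.root)
        return out


def resample_support(
    matrix: ProductScoreMatrix,
    mode: str = "bootstrap",
    replicates: int = 1000,
    seed: int = 0,
    method: str = "nj",
) -> SupportTree:
    """Branch support by resampling profile columns of the N x M matrix.

    ``bootstrap`` draws M columns with replacement; ``jackknife80`` draws
    floor(0.8 M) columns without replacement.  Support of an internal
    branch of the point-estimate tree is the percentage of replicate trees
    containing its bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    n_cols = matrix.values.shape[1]
    if n_cols < 2:
        raise ValueError("need at least 2 matrix columns to resample")
    if mode not in ("bootstrap", "jackknife80"):
        raise ValueError("mode must be 'bootstrap' or 'jackknife80'")
    build = TREE_BACKENDS[method]

    point_tree = build(euclidean_distances(matrix))
    target_splits = point_tree.bipartitions()
    counts = {split: 0 for split in target_splits}
    rng = np.random.default_rng(seed)
    ids = list(matrix.row_ids)

    for _ in range(replicates):
        if mode == "bootstrap":
            cols = rng.integers(0, n_cols, size=n_cols)
        else:
            cols = rng.permutation(n_cols)[: int(0.8 * n_cols)]
        sub = matrix.values[:, cols]
        gram = sub @ sub.T
        sq = np.diag(gram)
        d = np.sqrt(np.clip(sq[:, None] + sq[None, :] - 2 * gram, 0.0, None))
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        rep_tree = build(DistanceMatrix(d, ids))
        rep_splits = rep_tree.bipartitions()
        for split in target_splits & rep_splits:
            counts[split] += 1

    supports = {s: 100.0 * c / replicates for s, c in counts.items()}
    return SupportTree(point_tree, supports)
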