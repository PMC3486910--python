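"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap.

The donor-inference chain needs (i) pairwise distances from amino-acid
alignments, (ii) Saitou-Nei neighbor-joining trees, (iii) column
bootstrap replicates, and (iv) leaf-to-leaf path metrics (internal-node
count, branch-length sum).  Everything is deterministic: NJ ties are
broken on the lexicographically smallest leaf labels of the joined
clusters, and bootstrap resampling is driven by an explicit seed.

Distance models: uncorrected p-distance (default) or its Poisson
correction ``-ln(1 - p)``; gaps are handled by pairwise or complete
deletion of gapped columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AlignmentSet
from .tree import PathMetrics, Tree, TreeNode

__all__ = [
    "DistanceMatrix",
    "pdistance_matrix",
    "nj_tree",
    "bootstrap_nj",
    "path_metrics",
    "tree_distance_matrix",
]

GAP = ord("-")


@dataclass
class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(self.d < 0):
            raise ValueError("distance matrix contains negative entries")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


def _encode(aln: AlignmentSet) -> tuple[list[str], np.ndarray]:
    labels = list(aln.sequences)
    arr = np.frombuffer(
        "".join(aln.sequences[l].upper() for l in labels).encode("ascii"), dtype=np.uint8
    ).reshape(len(labels), aln.n_columns)
    return labels, arr


def pdistance_matrix(
    aln: AlignmentSet,
    gap_handling: str = "pairwise_deletion",
    model: str = "p",
) -> DistanceMatrix:
    """Pairwise distances from an alignment.

    ``gap_handling`` is ``"pairwise_deletion"`` (per pair, drop columns
    gapped in either sequence) or ``"complete_deletion"`` (drop columns
    gapped in any sequence).  ``model`` is ``"p"`` (proportion of
    differing comparable columns) or ``"poisson"`` (``-ln(1-p)``).
    A pair with no comparable columns is an error.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least two sequences")
    if gap_handling not in ("pairwise_deletion", "complete_deletion"):
        raise ValueError(f"unknown gap handling {gap_handling!r}")
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")

    labels, arr = _encode(aln)
    not_gap = arr != GAP
    if gap_handling == "complete_deletion":
        keep = not_gap.all(axis=0)
        if not keep.any():
            raise ValueError("complete deletion removed every column")
        arr = arr[:, keep]
        not_gap = np.ones_like(arr, dtype=bool)

    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = not_gap[i] & not_gap[j]
            n_comp = int(comparable.sum())
            if n_comp == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = float(((arr[i] != arr[j]) & comparable).sum()) / n_comp
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson correction undefined at p=1 for {labels[i]!r}/{labels[j]!r}"
                    )
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=labels, d=d)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimising
    ``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``; branch
    lengths use the standard NJ formulas with negative values clamped
    to zero and the deficit moved to the sister branch.  The output is
    unrooted (trifurcating root node).  Ties in Q are resolved on the
    lexicographically smallest leaf labels of the joined clusters.
    """
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    keys: list[str] = list(dm.labels)  # smallest leaf label per cluster
    D = dm.d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = [
            (i, j) for i in range(m) for j in range(i + 1, m) if Q[i, j] <= qmin + 1e-12
        ]
        i, j = min(candidates, key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))))
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])

        dk = 0.5 * (D[i] + D[j] - dij)
        dk = np.maximum(dk, 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = dk[keep]
        D = newD
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final three-way join (three-point formulas)
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        max(0.0, (d01 + d02 - d12) / 2.0),
        max(0.0, (d01 + d12 - d02) / 2.0),
        max(0.0, (d02 + d12 - d01) / 2.0),
    )
    root = TreeNode()
    for node, length in zip(nodes, lengths):
        node.length = length
        root.add_child(node)
    return Tree(root)


def bootstrap_nj(
    aln: AlignmentSet,
    replicates: int = 2000,
    seed: int | None = None,
    gap_handling: str = "pairwise_deletion",
    model: str = "p",
) -> list[Tree]:
    """Column-bootstrap NJ trees.

    Each replicate resamples alignment columns with replacement (same
    length), recomputes distances, and rebuilds the NJ tree.  Fully
    reproducible for a given ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    labels, arr = _encode(aln)
    n_cols = arr.shape[1]
    trees = []
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        sub = arr[:, cols]
        sub_aln = AlignmentSet(
            sequences={l: sub[i].tobytes().decode("ascii") for i, l in enumerate(labels)}
        )
        trees.append(nj_tree(pdistance_matrix(sub_aln, gap_handling=gap_handling, model=model)))
    return trees


def path_metrics(tree: Tree, leaf_a: str, leaf_b: str) -> PathMetrics:
    """Internal-node count and branch-length sum between two leaves."""
    return tree.path_metrics(leaf_a, leaf_b)


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    labels = tree.leaf_labels
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.path_metrics(labels[i], labels[j]).branch_length_sum
    return DistanceMatrix(labels=labels, d=d)
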