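"""Distance-based phylogeny of precursor peptides.

Distances are 1 - global-alignment identity fraction; trees are built
with Saitou-Nei neighbor-joining and exported as Newick plus a flat
leaf-annotation table (group, subgroup, GRAVY) importable by standard
tree viewers. Trees are unrooted (serialized with a basal
trifurcation); negative branch-length estimates are clamped to zero and
flagged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .align import AlignmentParams, global_identity_fraction


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m


def distance_matrix(ids: list[str], sequences: list[str],
                    params: AlignmentParams = AlignmentParams()) -> DistanceMatrix:
    """d(i, j) = 1 - identity fraction of the global pairwise alignment."""
    n = len(ids)
    if len(sequences) != n:
        raise ValueError("ids and sequences differ in length")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - global_identity_fraction(sequences[i], sequences[j], params)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(ids=list(ids), matrix=m)


@dataclass
class TreeNode:
    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _bl in self.children:
            out.extend(child.leaf_names())
        return out

    def newick(self, digits: int = 9) -> str:
        return self._newick_inner(digits) + ";"

    def _newick_inner(self, digits: int) -> str:
        if self.is_leaf():
            return self.name
        parts = [
            f"{child._newick_inner(digits)}:{bl:.{digits}f}"
            for child, bl in self.children
        ]
        return "(" + ",".join(parts) + ")"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits (as the smaller-or-lexicographic leaf side)."""
        all_leaves = frozenset(self.leaf_names())
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, _bl in node.children:
                side = walk(child)
                if 1 < len(side) < len(all_leaves) - 1:
                    other = all_leaves - side
                    splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
                below = below | side
            return below

        walk(self)
        return splits


@dataclass
class PhyloTree:
    root: TreeNode  # basal trifurcation for an unrooted tree
    clamped_branches: int = 0
    leaf_annotations: dict = field(default_factory=dict)
    two_taxon: bool = False


def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing the Q-criterion
    Q(i,j) = (n-2) d(i,j) - r_i - r_j; ties resolve to the smallest
    (i, j) taxon-index pair. Branch lengths follow the standard NJ
    formulas; on additive matrices the generating tree is recovered
    exactly. Fewer than 3 taxa: two taxa yield a flagged two-leaf tree,
    fewer is an error.
    """
    n = len(D.ids)
    if n < 2:
        raise ValueError("neighbor joining requires at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.ids]
    if n == 2:
        root = TreeNode(children=[(nodes[0], D.matrix[0, 1] / 2.0),
                                  (nodes[1], D.matrix[0, 1] / 2.0)])
        return PhyloTree(root=root, two_taxon=True)

    d = D.matrix.copy()
    active = list(range(n))
    clamped = 0

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _q, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, clamped = 0.0, clamped + 1
        if lj < 0:
            lj, clamped = 0.0, clamped + 1
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new internal node to every other active taxon
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - dij)
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    # three-point formulas for the final star
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    lengths = []
    for val in (li, lj, lk):
        if val < 0:
            val, clamped = 0.0, clamped + 1
        lengths.append(val)
    root = TreeNode(children=[(nodes[i], lengths[0]),
                              (nodes[j], lengths[1]),
                              (nodes[k], lengths[2])])
    return PhyloTree(root=root, clamped_branches=clamped)


def write_leaf_annotations(tree: PhyloTree, path) -> None:
    import pandas as pd

    rows = []
    for leaf in sorted(tree.root.leaf_names()):
        ann = tree.leaf_annotations.get(leaf, {})
        rows.append(
            {
                "id": leaf,
                "group_id": ann.get("group_id", ""),
                "subgroup": ann.get("subgroup", ""),
                "GRAVY": ann.get("gravy", ""),
            }
        )
    pd.DataFrame(rows, columns=["id", "group_id", "subgroup", "GRAVY"]).to_csv(
        path, sep="\t", index=False
    )
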