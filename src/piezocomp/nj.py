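"""Neighbor-joining tree construction from a distance matrix.

Classic Saitou–Nei agglomeration with the Studier–Keppler Q criterion:
at each step the pair (i, j) minimising
``Q(i, j) = (n - 2) d(i, j) - r_i - r_j`` (with r the row sums) is joined;
pendant branch lengths follow the standard formulas and the final three
nodes are joined to one internal vertex, giving the usual unrooted tree.
Ties in Q are broken by the lowest pair of node indices in insertion order,
so the join sequence is deterministic. Negative branch lengths are clamped
to zero with the deficit moved to the sister branch, preserving the path
length between the joined nodes.

On a matrix that is exactly additive on some tree, neighbor joining
reconstructs that tree's topology and branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .composition import DistanceMatrix


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; children carry their branch lengths."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree represented with an arbitrary internal root node."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name or "" for leaf in self.root.leaves()]

    def to_newick(self) -> str:
        return _newick(self.root) + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits of the leaf set, one per internal edge.

        Each split is represented by the smaller-or-lexicographic side, so
        two trees over the same leaves are topologically equal iff their
        bipartition sets are equal.
        """
        all_leaves = frozenset(self.leaf_names)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name or ""])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                splits.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        for child, _ in self.root.children:
            walk(child)
        return splits

    def distance_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix induced by the tree."""
        names = self.leaf_names
        index = {n: i for i, n in enumerate(names)}
        d = np.zeros((len(names), len(names)))

        def walk(node: TreeNode, dist_to_root: float, acc: dict[str, float]) -> None:
            if node.is_leaf:
                acc[node.name or ""] = dist_to_root
                return
            for child, bl in node.children:
                walk(child, dist_to_root + bl, acc)

        # distances via per-subtree accumulation from every node acting as root
        # of its subtree: combine children pairwise
        def pairs(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name or "": 0.0}
            below: list[dict[str, float]] = []
            for child, bl in node.children:
                sub = pairs(child)
                below.append({k: v + bl for k, v in sub.items()})
            for da, db in combinations(below, 2):
                for na, va in da.items():
                    for nb, vb in db.items():
                        d[index[na], index[nb]] = d[index[nb], index[na]] = va + vb
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        pairs(self.root)
        return DistanceMatrix(names, d)


def _newick(node: TreeNode) -> str:
    if node.is_leaf:
        return node.name or ""
    inner = ",".join(f"{_newick(c)}:{bl:.10g}" for c, bl in node.children)
    return f"({inner})"


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Build the neighbor-joining tree of a distance matrix (>= 3 taxa)."""
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]
    order: list[int] = list(range(n0))  # insertion-order ids for tie-breaks
    next_id = n0
    d = dm.values.astype(float).copy()
    active = list(range(n0))

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [
            (order[active[i]], order[active[j]], i, j)
            for i, j in zip(*np.nonzero(np.isclose(q, qmin, rtol=0, atol=1e-12)))
            if i < j
        ]
        _, _, i, j = min(candidates)
        ai, aj = active[i], active[j]
        dij = d[ai, aj]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)

        parent = TreeNode(children=[(nodes[ai], li), (nodes[aj], lj)])
        nodes.append(parent)
        order.append(next_id)
        next_id += 1
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (ai, aj):
                continue
            new_row[k] = 0.5 * (d[ai, k] + d[aj, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : new_row.size - 1] = new_row[:-1]
        d[: new_row.size - 1, -1] = new_row[:-1]
        active = [k for k in active if k not in (ai, aj)] + [d.shape[0] - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = _clamp_triple(la, lb, lc)
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return Tree(root=root)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _clamp_triple(la: float, lb: float, lc: float) -> tuple[float, float, float]:
    vals = [la, lb, lc]
    deficit = sum(v for v in vals if v < 0)
    vals = [max(v, 0.0) for v in vals]
    if deficit:
        # spread the deficit over the positive branches, floored at zero
        pos = [i for i, v in enumerate(vals) if v > 0]
        if pos:
            share = deficit / len(pos)
            vals = [max(v + share, 0.0) if i in pos else v for i, v in enumerate(vals)]
    return vals[0], vals[1], vals[2]
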