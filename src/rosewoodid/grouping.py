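"""Neighbor-joining trees and monophyly checks.

A lightweight sanity layer: build a Saitou–Nei NJ tree from the K2P
distance matrix and test whether labeled groups form clades relative to an
outgroup. This validates group structure quickly; it is not a substitute
for full likelihood or Bayesian phylogenetics.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np

from .distances import DistanceMatrix


class GroupingError(ValueError):
    pass


class _Node:
    __slots__ = ("label", "children")  # children: list of (child, branchlen)

    def __init__(self, label=None):
        self.label = label
        self.children = []

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{max(0.0, bl):.12g}"
                         for c, bl in self.children)
        return f"({inner})"


def nj_newick(dm: DistanceMatrix) -> str:
    """Canonical Saitou–Nei neighbor joining; returns a newick string.

    Deterministic: Q-matrix ties are broken toward the lowest-index pair.
    Negative branch lengths (possible on non-additive input) are clamped
    to zero on output.
    """
    n = len(dm.ids)
    if n < 3:
        raise GroupingError("need >=3 ids for an unrooted NJ tree")
    if not dm.defined.all():
        bad = [(dm.ids[i], dm.ids[j])
               for i in range(n) for j in range(i + 1, n)
               if not dm.defined[i, j]]
        raise GroupingError(f"undefined distances present: {bad[:5]}")
    d = dm.matrix.astype(float).copy()
    nodes = [_Node(sid) for sid in dm.ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best, best_q = None, math.inf
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        u = _Node()
        u.children = [(nodes[i], li), (nodes[j], lj)]
        # extend matrix with the new node
        d = np.pad(d, ((0, 1), (0, 1)))
        new = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(u)
        active = [k for k in active if k not in (i, j)] + [new]
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = _Node()
    root.children = [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    return root.newick() + ";"


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """NJ tree as a dendropy Tree (unrooted, trifurcating at the root)."""
    tree = dendropy.Tree.get(data=nj_newick(dm), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick",
                             preserve_underscores=True)


def is_monophyletic(tree, ids, outgroup_ids=()) -> bool:
    """Do ``ids`` form a clade in the tree rooted via the outgroup?

    ``tree`` is a dendropy Tree or a newick string. With an outgroup, the
    test is bipartition-based on the unrooted topology: ``ids`` are
    monophyletic iff some edge separates exactly ``ids`` from the rest and
    the outgroup lies on the other side. Without an outgroup the tree is
    midpoint-rooted first.
    """
    t = _as_tree(tree)
    leaves = {lf.taxon.label for lf in t.leaf_node_iter()}
    ids = set(ids)
    outgroup_ids = set(outgroup_ids)
    if not ids <= leaves:
        raise GroupingError(f"ids not in tree: {sorted(ids - leaves)}")
    if outgroup_ids and not outgroup_ids <= leaves:
        raise GroupingError(
            f"outgroup not in tree: {sorted(outgroup_ids - leaves)}")
    if len(ids) <= 1 or ids == leaves:
        return True
    if not outgroup_ids:
        t = _as_tree(t.as_string(schema="newick"))  # work on a copy
        t.reroot_at_midpoint(update_bipartitions=False)
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == ids and not (outgroup_ids & below):
            return True
        # unrooted: the complement side of the edge is also a candidate
        if outgroup_ids and (leaves - below) == ids:
            return True
    return False
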