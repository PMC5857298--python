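"""Neighbor-joining tree reconstruction and tree utilities.

Classical Saitou-Nei neighbor joining, implemented here rather than taken
from a library so that the tie-breaking and negative-branch handling are
fully specified:

* at each step the pair minimizing the Q-criterion is joined; exact ties
  are broken by the lexicographically smallest (sorted) label pair, where
  an internal node carries the smallest leaf label of its clade;
* a negative branch-length estimate is clamped to 0 and the deficit moved
  to the sister branch, preserving their sum.

Trees are scikit-bio :class:`~skbio.TreeNode` objects (unrooted, with the
final three lineages attached to a trifurcating root) and serialize to
Newick.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import ValidationError


def _join(u: TreeNode, v: TreeNode, lu: float, lv: float) -> TreeNode:
    u.length = lu
    v.length = lv
    return TreeNode(children=[u, v])


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Build the unrooted neighbor-joining tree for a distance matrix."""
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValidationError("neighbor joining needs at least 3 labels")
    D = np.array(dm.data, dtype=float)
    if not np.isfinite(D).all():
        raise ValidationError("distance matrix contains non-finite entries")

    nodes = [TreeNode(name=lab) for lab in labels]
    keys = list(labels)  # smallest leaf label within each active clade

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = {
            (min(i, j), max(i, j))
            for i, j in zip(*np.where(Q == qmin))
            if i != j
        }
        _, _, i, j = min(
            tuple(sorted((keys[i], keys[j]))) + (i, j) for i, j in candidates
        )
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        if li < 0.0:
            li, lj = 0.0, dij
        elif lj < 0.0:
            li, lj = dij, 0.0
        new_node = _join(nodes[i], nodes[j], li, lj)
        new_key = min(keys[i], keys[j])
        d_new = 0.5 * (D[i, :] + D[j, :] - dij)

        keep = [k for k in range(n) if k not in (i, j)]
        D = D[np.ix_(keep, keep)]
        d_new = d_new[keep]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = d_new
        D[:-1, -1] = d_new
        nodes = [nodes[k] for k in keep] + [new_node]
        keys = [keys[k] for k in keep] + [new_key]

    # final trifurcation: closed-form branch lengths
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    root = TreeNode(children=[a, b, c])
    return root


def to_newick(tree: TreeNode) -> str:
    return str(tree)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path))


def bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Non-trivial splits of the unrooted tree, as unordered leaf-set pairs."""
    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    splits: set[frozenset[frozenset[str]]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(frozenset({side, all_leaves - side}))
    return splits


def same_topology(t1: TreeNode, t2: TreeNode) -> bool:
    """True iff the two unrooted trees induce identical leaf bipartitions."""
    l1 = frozenset(leaf.name for leaf in t1.tips())
    l2 = frozenset(leaf.name for leaf in t2.tips())
    if l1 != l2:
        return False
    return bipartitions(t1) == bipartitions(t2)


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> int:
    """Symmetric-difference (Robinson-Foulds) distance on bipartitions."""
    return len(bipartitions(t1) ^ bipartitions(t2))


def clade_check(tree: TreeNode, group: set[str]) -> bool:
    """True iff some edge bipartitions the leaves exactly into group vs rest."""
    leaves = {leaf.name for leaf in tree.tips()}
    group = set(group)
    if not group or not group.issubset(leaves):
        raise ValidationError("group must be a non-empty subset of the leaves")
    if group == leaves:
        raise ValidationError("group covering all leaves is a trivial bipartition")
    if len(group) == 1 or len(group) == len(leaves) - 1:
        return True  # pendant edge
    target = frozenset(group)
    complement = frozenset(leaves - group)
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if side == target or side == complement:
            return True
    return False


def tip_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix (additive distances of the tree)."""
    return tree.tip_tip_distances()
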