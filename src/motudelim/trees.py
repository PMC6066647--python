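"""Neighbour-joining tree construction and clade-exclusivity assessment.

The NJ implementation follows the Saitou–Nei/Studier–Keppler agglomeration
on the Q criterion and is fully deterministic: ties in Q are broken by the
lexicographically smallest pair of cluster keys (a cluster's key is the
smallest specimen id among its tips).  Negative branch-length estimates are
clamped to zero with the deficit transferred to the sibling branch, the
standard practical convention.

Trees are returned as :class:`dendropy.Tree` objects so that callers get
Newick I/O, rerooting and traversal for free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .io import BarcodeLibrary


class TreeError(ValueError):
    pass


class _Node:
    __slots__ = ("children", "tip", "key")

    def __init__(self, tip: str | None, children=None):
        self.tip = tip
        self.children = children or []  # list of (node, branch_length)
        self.key = tip if tip else min(c.key for c, _ in self.children)

    def newick(self) -> str:
        if self.tip is not None:
            return _quote(self.tip)
        inner = ",".join(
            f"{c.newick()}:{max(bl, 0.0):.10g}" for c, bl in self.children
        )
        return f"({inner})"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _clamp(li: float, lj: float) -> tuple[float, float]:
    # Clamp negatives to 0, moving the deficit onto the sibling branch.
    if li < 0.0:
        lj = max(lj + li, 0.0)
        li = 0.0
    if lj < 0.0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def neighbor_joining(matrix: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted NJ tree from a symmetric distance matrix."""
    n = len(matrix)
    if n < 3:
        raise TreeError("neighbour joining needs at least 3 specimens")
    if not np.allclose(matrix.values, matrix.values.T):
        raise TreeError("matrix is not symmetric")
    if not np.all(np.isfinite(matrix.values)):
        raise TreeError("saturated (infinite) distances; NJ undefined")

    D = matrix.values.astype(float).copy()
    nodes: list[_Node] = [_Node(tip=i) for i in matrix.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    key = tuple(
                        sorted((nodes[active[a]].key, nodes[active[b]].key))
                    )
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        ia, ib = active[a], active[b]
        dab = sub[a, b]
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        la, lb = _clamp(la, lb)
        parent = _Node(tip=None, children=[(nodes[ia], la), (nodes[ib], lb)])
        # distances from the new node to the remaining clusters
        new_row = 0.5 * (D[ia, :] + D[ib, :] - dab)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        k = len(nodes) - 1
        active = [x for x in active if x not in (ia, ib)] + [k]

    # three-point closure for the final trifurcation
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    parts = sorted(
        [(nodes[i], li), (nodes[j], lj), (nodes[k], lk)],
        key=lambda t: t[0].key,
    )
    inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in parts)
    newick = f"({inner});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths at 6 significant digits."""
    clone = tree.clone(depth=1)
    for edge in clone.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(f"{edge.length:.6g}")
    return clone.as_string(schema="newick", suppress_rooting=True).strip()


def _tip_sets(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Tip-label set under every edge (both sides of each bipartition)."""
    all_tips = frozenset(
        leaf.taxon.label for leaf in tree.leaf_node_iter()
    )
    sets = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tipset = frozenset([node.taxon.label])
        else:
            node._tipset = frozenset().union(
                *(c._tipset for c in node.child_nodes())
            )
        sets.append(node._tipset)
        sets.append(all_tips - node._tipset)
    return sets


@dataclass
class ExclusivityReport:
    per_species: dict[str, bool]
    fraction: float


def clade_exclusivity(
    tree: dendropy.Tree, library: BarcodeLibrary
) -> ExclusivityReport:
    """Which morphospecies are exclusive (form their own clade) on the tree.

    A species is exclusive when some edge bipartition isolates exactly its
    specimens; singletons are exclusive by definition.  The test uses both
    sides of every bipartition so the verdict does not depend on rooting.
    """
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    sets = set(_tip_sets(tree))
    species = library.species_of()
    verdict = {}
    for label, members in species.items():
        mem = frozenset(m for m in members if m in tip_labels)
        if not mem:
            continue
        verdict[label] = len(mem) == 1 or mem in sets
    fraction = sum(verdict.values()) / len(verdict)
    return ExclusivityReport(per_species=verdict, fraction=fraction)
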