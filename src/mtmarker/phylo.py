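"""Distance-based strain trees.

The question a marker answers is *distinguishability*: do eight strains give
eight distinct leaves?  For that purpose p-distances plus neighbor joining
are sufficient and fully deterministic — NJ is exact on additive distance
matrices, and ties are broken by the lowest (i, j) index pair so the same
input always yields the same tree.  Likelihood-based inference is
deliberately out of scope.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode


class DistanceError(ValueError):
    """Raised for invalid or incomparable distance inputs."""


def p_distance_matrix(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances (mismatches / compared sites) between sequences.

    Sequences must be equal-length (haplotypes over a shared window, or
    whole genomes reconstructed on shared coordinates).  Sites where either
    sequence has N are excluded from both numerator and denominator; a pair
    with zero comparable sites raises :class:`DistanceError`.
    """
    labels = list(seqs)
    if len(labels) < 2:
        raise DistanceError("need at least 2 sequences")
    length = len(seqs[labels[0]])
    if any(len(seqs[lb]) != length for lb in labels):
        raise DistanceError("sequences must have equal length")
    arr = np.array([list(seqs[lb].upper()) for lb in labels])
    known = arr != "N"
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = known[i] & known[j]
            m = int(comparable.sum())
            if m == 0:
                raise DistanceError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            diff = int((arr[i, comparable] != arr[j, comparable]).sum())
            d[i, j] = d[j, i] = diff / m
    return labels, d


def nj_tree(labels: list[str], d: np.ndarray) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Standard agglomeration with the Q criterion; when several pairs tie, the
    lexicographically smallest active (i, j) index pair is joined, so the
    result is deterministic in the input order.  Negative branch lengths are
    clamped to zero.  The tree is returned rooted at the final join for
    serialization but should be interpreted as unrooted.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise DistanceError("matrix shape does not match label count")
    if not np.allclose(d, d.T):
        raise DistanceError("distance matrix must be symmetric")
    if len(set(labels)) != n:
        raise DistanceError("duplicate labels")
    if n < 2:
        raise DistanceError("need at least 2 taxa")

    nodes = [TreeNode(name=lb) for lb in labels]
    if n == 2:
        half = max(d[0, 1] / 2.0, 0.0)
        for node in nodes:
            node.length = half
        return TreeNode(children=nodes)

    D = d.copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among minimizers
        qmin = q.min()
        ii, jj = np.argwhere(np.isclose(q, qmin, rtol=0.0, atol=1e-12))[0]
        if ii > jj:
            ii, jj = jj, ii
        a, b = active[ii], active[jj]
        dij = D[a, b]
        la = 0.5 * dij + (totals[ii] - totals[jj]) / (2.0 * (m - 2))
        lb = dij - la
        nodes[a].length = max(la, 0.0)
        nodes[b].length = max(lb, 0.0)
        parent = TreeNode(children=[nodes[a], nodes[b]])
        # distances from the new node to every remaining active node
        new_row = np.zeros(D.shape[0] + 1)
        for kk in active:
            if kk in (a, b):
                continue
            new_row[kk] = 0.5 * (D[a, kk] + D[b, kk] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [len(nodes) - 1]

    a, b = active
    edge = max(D[a, b], 0.0)
    # attach the last pair; split the remaining edge evenly for display
    nodes[a].length = edge / 2.0
    nodes[b].length = edge / 2.0
    return TreeNode(children=[nodes[a], nodes[b]])


def resolution_count(seqs: dict[str, str] | np.ndarray) -> int:
    """Number of distinct entities: equivalence classes under exact sequence
    identity (mapping input) or zero distance (matrix input)."""
    if isinstance(seqs, dict):
        if not seqs:
            raise ValueError("need at least one entity")
        return len(set(seqs.values()))
    d = np.asarray(seqs, dtype=float)
    n = d.shape[0]
    if n == 0:
        raise ValueError("need at least one entity")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] == 0.0:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    return len({find(x) for x in range(n)})


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree as canonical frozensets."""
    leaves = frozenset(t.name for t in tree.tips())
    parts: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            parts.add(frozenset((side, leaves - side)))
    # the root of a rooted representation splits its children: cover the
    # bipartition induced by each root child subtree as well
    for child in tree.children:
        side = frozenset(t.name for t in child.tips())
        if 1 < len(side) < len(leaves) - 1:
            parts.add(frozenset((side, leaves - side)))
    return parts


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Unrooted Robinson–Foulds distance: bipartitions in exactly one tree."""
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise DistanceError("trees have different leaf sets")
    return len(_bipartitions(t1) ^ _bipartitions(t2))


def distance_frame(labels: list[str], d: np.ndarray):
    """TSV-ready DataFrame view of a distance matrix."""
    import pandas as pd

    return pd.DataFrame(d, index=labels, columns=labels)
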