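"""Distance-based gene trees: neighbor-joining and cluster-separation checks.

Canonical Saitou-Nei neighbor-joining over a precomputed distance matrix,
with deterministic tie-breaking (equal Q-criterion values resolve by the
lexicographic order of the joined clusters' smallest leaf labels) and negative
branch-length estimates clamped to zero with the clamped amount logged. The
result is an unrooted dendropy tree (trifurcating seed node), so Newick export
and topology comparisons come for free.

The separation check asks a purely topological question standing in for node
support: does a nominated set of leaves form one side of a bipartition of the
tree, i.e. a clade once the tree is rooted at a given outgroup?
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .distance import DistanceMatrix
from .errors import InputError, SaturationError

logger = logging.getLogger(__name__)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Raises :class:`SaturationError` when any cell is NaN (an undefined,
    saturated distance), naming the offending pair.
    """
    n = len(dm.labels)
    if n < 3:
        raise InputError("neighbor-joining needs at least 3 labels")
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isfinite(dm.values[i, j]):
                raise SaturationError(
                    f"distance undefined for pair ({dm.labels[i]}, {dm.labels[j]})"
                )

    tns = dendropy.TaxonNamespace(list(dm.labels))
    nodes = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)
    # representative label per active node, for deterministic tie-breaking
    reps = list(dm.labels)
    d = dm.values.astype(float).copy()
    active = list(range(n))
    clamped_total = 0.0

    def _join(i: int, j: int, li: float, lj: float) -> None:
        nonlocal clamped_total
        parent = dendropy.Node()
        for idx, ln in ((i, li), (j, lj)):
            if ln < 0:
                clamped_total += -ln
                logger.info("clamped negative NJ branch length %.6g to 0", ln)
                ln = 0.0
            nodes[idx].edge.length = ln
            parent.add_child(nodes[idx])
        nodes.append(parent)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        _join(i, j, li, lj)
        # grow the distance matrix with the new node u
        u = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    seed = dendropy.Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        if ln < 0:
            clamped_total += -ln
            logger.info("clamped negative NJ branch length %.6g to 0", ln)
            ln = 0.0
        nodes[idx].edge.length = ln
        seed.add_child(nodes[idx])
    if clamped_total:
        logger.info("total negative branch length clamped: %.6g", clamped_total)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    return tree


def _leaf_labels(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def is_exclusive_cluster(tree: dendropy.Tree, taxa, outgroup: str) -> bool:
    """True iff ``taxa`` is exactly a clade after rooting on ``outgroup``.

    Equivalently: some edge of the unrooted tree bipartitions the leaves into
    ``taxa`` versus everything else (the outgroup on the other side).
    """
    taxa = frozenset(taxa)
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    unknown = (taxa | {outgroup}) - all_leaves
    if unknown:
        raise InputError(f"labels not in tree: {sorted(unknown)}")
    if outgroup in taxa:
        raise InputError("outgroup must not be a member of the tested cluster")
    if not taxa:
        raise InputError("empty cluster")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = _leaf_labels(node)
        if side == taxa or (all_leaves - side) == taxa:
            return True
    return False
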