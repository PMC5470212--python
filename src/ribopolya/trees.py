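"""Sample dendrograms from expression profiles.

Euclidean distances between per-sample expression vectors (on log2(x+1)
values by default — raw-TPM distances are dominated by a handful of very
highly expressed genes) followed by neighbour joining.  Trees built this way
should group samples by biology rather than by library type once TPM
estimates have been corrected.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .expression import ExpressionMatrix

__all__ = ["euclidean_distances", "neighbour_joining"]


def euclidean_distances(
    matrix: ExpressionMatrix, transform: str = "log2p1"
) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample expression vectors.

    ``transform="log2p1"`` applies log2(x+1) first; ``"none"`` uses raw TPM.
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("need >= 2 samples")
    values = matrix.values.to_numpy(dtype=float).T  # samples x genes
    if transform == "log2p1":
        values = np.log2(values + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    d = squareform(pdist(values, metric="euclidean"))
    return DistanceMatrix(d, ids=matrix.sample_ids)


def _tree_from_children(children: dict, lengths: dict, root_key) -> TreeNode:
    node = TreeNode(name=root_key if isinstance(root_key, str) else None)
    node.length = lengths.get(root_key)
    for child in children.get(root_key, []):
        node.append(_tree_from_children(children, lengths, child))
    return node


def neighbour_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical Saitou-Nei neighbour joining.

    The Q-matrix is minimised at each step, ties broken by the smallest
    (i, j) label-index pair; branch lengths use the standard two-point
    formulas, with negative estimates clamped to zero and the residual moved
    to the sibling edge so path lengths are preserved.  The unrooted result
    is returned as a :class:`skbio.TreeNode` with a trifurcating root for
    more than three taxa; two taxa yield a single edge carrying the full
    distance.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    d = np.asarray(dm.data, dtype=float).copy()
    if (np.diag(d) != 0).any() or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    if n == 2:
        root = TreeNode()
        a = TreeNode(name=labels[0])
        a.length = float(d[0, 1])
        b = TreeNode(name=labels[1])
        b.length = 0.0
        root.extend([a, b])
        return root

    # active nodes: keys are label strings (tips) or internal ints
    children: dict = {}
    lengths: dict = {}
    active: list = list(labels)
    next_internal = 0

    while len(active) > 3:
        m = len(active)
        row_sums = d.sum(axis=1)
        q = (m - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties resolved by smallest (i, j) index pair
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or q[i, j] < q[best] - 1e-12:
                    best = (i, j)
        i, j = best
        li = d[i, j] / 2 + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        # clamp negatives, moving the residual to the sibling edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new_key = ("node", next_internal)
        next_internal += 1
        children[new_key] = [active[i], active[j]]
        lengths[active[i]] = float(li)
        lengths[active[j]] = float(lj)

        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        active = [active[k] for k in keep] + [new_key]

    # final three nodes joined at an unrooted trifurcation
    if len(active) == 3:
        a = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
        b = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
        c = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
        root_key = ("root", 0)
        children[root_key] = list(active)
        for node, length in zip(active, (a, b, c)):
            lengths[node] = float(max(length, 0.0))
    else:  # two remaining (can happen only when the loop never ran on n == 3? keep safe)
        root_key = ("root", 0)
        children[root_key] = list(active)
        lengths[active[0]] = float(d[0, 1])
        lengths[active[1]] = 0.0

    tree = _tree_from_children(children, lengths, root_key)
    tree.length = None
    return tree
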