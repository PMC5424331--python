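"""UPGMA phenograms from pairwise distance matrices, with Newick export.

UPGMA (unweighted pair-group method with arithmetic mean) agglomerates
the two closest clusters at each step, placing the merge node at half the
clusters' average pairwise distance, so the tree is ultrametric: every
leaf is equidistant from the root.  Applied here to the Mahalanobis
distance matrix between species mean shapes, it summarises phenetic
similarity of wing form.

Ties in the minimum pairwise distance are broken by lexicographic label
order (logged), making the tree deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Dendrogram", "upgma", "to_newick"]


@dataclass
class _Node:
    height: float  # merge height (half the cluster distance); 0 for leaves
    label: str | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    leaves: tuple = ()


@dataclass
class Dendrogram:
    """Rooted ultrametric binary tree over group labels.

    ``merges`` records each agglomeration as
    (left labels, right labels, height, size); heights are half the
    average inter-cluster distance and non-decreasing from leaves to root.
    """

    labels: list
    root: _Node
    merges: list  # [(tuple, tuple, height, size), ...]

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Pairwise cophenetic distances (2 x height of the joining node)."""
        g = len(self.labels)
        index = {l: i for i, l in enumerate(self.labels)}
        D = np.zeros((g, g))

        def visit(node: _Node):
            if node.label is not None:
                return
            for a in node.left.leaves:
                for b in node.right.leaves:
                    i, j = index[a], index[b]
                    D[i, j] = D[j, i] = 2.0 * node.height
            visit(node.left)
            visit(node.right)

        visit(self.root)
        return pd.DataFrame(D, index=self.labels, columns=self.labels)

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "left": "+".join(map(str, l)),
                    "right": "+".join(map(str, r)),
                    "height": h,
                    "size": s,
                }
                for l, r, h, s in self.merges
            ]
        )

    def newick(self) -> str:
        return to_newick(self)


def upgma(dist, labels=None) -> Dendrogram:
    """Average-linkage agglomeration of a symmetric distance matrix.

    ``dist`` may be a DataFrame (labels from its index) or an array with
    ``labels`` given separately.  The distance between a merged cluster
    AB and any C is the size-weighted average
    (|A| d(A,C) + |B| d(B,C)) / (|A| + |B|); merge heights are half the
    merged clusters' distance.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        if labels is None:
            labels = [f"g{i + 1}" for i in range(len(D))]
        labels = list(labels)
    g = len(labels)
    if D.shape != (g, g) or g < 2:
        raise ValueError("need a square distance matrix over >= 2 labels")
    if not np.allclose(D, D.T, atol=0.0):
        raise ValueError("distance matrix must be exactly symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be nonnegative")

    clusters: list[_Node] = [
        _Node(height=0.0, label=l, leaves=(l,)) for l in labels
    ]
    dmat = D.copy()
    active = list(range(g))
    merges = []

    while len(active) > 1:
        best = None
        best_d = np.inf
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = dmat[i, j]
                if d < best_d:
                    best_d = d
                    best = (ai, aj)
                elif d == best_d:
                    # lexicographic tie rule on the sorted leaf-label tuples
                    cand = tuple(sorted(clusters[i].leaves + clusters[j].leaves))
                    cur_i, cur_j = active[best[0]], active[best[1]]
                    cur = tuple(
                        sorted(clusters[cur_i].leaves + clusters[cur_j].leaves)
                    )
                    if cand < cur:
                        logger.info(
                            "tie at distance %g broken lexicographically", d
                        )
                        best = (ai, aj)
        ai, aj = best
        i, j = active[ai], active[aj]
        size_i, size_j = len(clusters[i].leaves), len(clusters[j].leaves)
        left, right = clusters[i], clusters[j]
        if right.leaves < left.leaves:
            left, right = right, left
        node = _Node(
            height=best_d / 2.0,
            left=left,
            right=right,
            leaves=tuple(sorted(left.leaves + right.leaves)),
        )
        merges.append((left.leaves, right.leaves, best_d / 2.0, size_i + size_j))
        # average-linkage update into slot i (sizes follow the slots)
        for a in active:
            if a in (i, j):
                continue
            new_d = (size_i * dmat[i, a] + size_j * dmat[j, a]) / (size_i + size_j)
            dmat[i, a] = dmat[a, i] = new_d
        clusters[i] = node
        active.remove(j)

    return Dendrogram(labels=labels, root=clusters[active[0]], merges=merges)


def to_newick(tree: Dendrogram, precision: int = 10) -> str:
    """Newick string with ultrametric branch lengths.

    Branch length of a child = parent height - child height, so every
    root-to-leaf path length equals the root height; parseable by any
    standard Newick reader.
    """

    def fmt(x: float) -> str:
        return f"{x:.{precision}g}"

    def render(node: _Node, parent_height: float) -> str:
        if node.label is not None:
            return f"{node.label}:{fmt(parent_height)}"
        inner = (
            f"({render(node.left, node.height)},{render(node.right, node.height)})"
        )
        if parent_height is None:
            return inner
        return f"{inner}:{fmt(parent_height - node.height)}"

    root = tree.root
    body = f"({render(root.left, root.height)},{render(root.right, root.height)})"
    return body + ";"
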