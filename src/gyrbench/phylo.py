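"""Kimura 2-parameter distances and neighbor-joining trees.

Marker amplicons are coordinate-homologous by construction (they span the
same primer-bounded region), so distance computation uses ungapped
end-to-end comparison when lengths match, and a pairwise end-to-end
alignment otherwise; sites with gaps or ambiguity codes are excluded
pairwise. The K2P distance distinguishes transitions (A<->G, C<->T) from
transversions: with transition fraction P and transversion fraction Q,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Neighbor joining follows the Saitou-Nei agglomeration; on additive distance
matrices it reconstructs the generating topology exactly. Negative branch
lengths are clamped to zero with the deficit moved to the sibling edge.
Trees are scikit-bio TreeNode objects and serialize to newick.
"""

from __future__ import annotations

import logging
from typing import Sequence

import edlib
import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from gyrbench.refdb import MarkerRecord

__all__ = [
    "SaturationError",
    "p_distance",
    "k2p_distance",
    "k2p_matrix",
    "neighbor_joining",
    "build_marker_tree",
]

logger = logging.getLogger(__name__)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_ACGT = set("ACGT")


class SaturationError(ValueError):
    """Substitution saturation: the K2P log arguments are non-positive."""


def _aligned(a: str, b: str) -> tuple[str, str]:
    if len(a) == len(b):
        return a, b
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    return nice["query_aligned"], nice["target_aligned"]


def _site_counts(a: str, b: str) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) with pairwise deletion."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    sites = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in _ACGT or y not in _ACGT:
            continue
        sites += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if sites == 0:
        raise ValueError("no comparable (ungapped, unambiguous) sites")
    return sites, ts, tv


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites (pairwise deletion of ambiguous sites)."""
    sites, ts, tv = _site_counts(a, b)
    return (ts + tv) / sites


def k2p_distance(a: str, b: str) -> float:
    """Kimura 2-parameter distance in substitutions per site."""
    sites, ts, tv = _site_counts(a, b)
    p, q = ts / sites, tv / sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair (P={p:.3f}, Q={q:.3f}): K2P distance undefined"
        )
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def k2p_matrix(
    sequences: Sequence[str], labels: Sequence[str], model: str = "K2P"
) -> DistanceMatrix:
    """Pairwise distance matrix under K2P or p-distance.

    Unequal-length pairs are end-to-end aligned first; gap columns are then
    excluded pairwise.
    """
    if len(sequences) != len(labels):
        raise ValueError("labels and sequences differ in length")
    dist = {"K2P": k2p_distance, "p-distance": p_distance}[model]
    n = len(sequences)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = _aligned(sequences[i], sequences[j])
            mat[i, j] = mat[j, i] = dist(a, b)
    return DistanceMatrix(mat, ids=list(labels))


def _pair_sort_key(node: TreeNode) -> str:
    """Deterministic node key: a leaf's name, or the smallest leaf below."""
    if node.is_tip():
        return node.name or ""
    return min(_pair_sort_key(c) for c in node.children)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted TreeNode.

    The Q-criterion minimum is tie-broken by the lexicographically smallest
    pair of node keys (a node's key is its smallest descendant label), making
    the topology deterministic. Negative branch lengths are clamped to zero
    and the deficit moved onto the sibling edge.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    d = np.asarray(dm.data, dtype=float).copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = np.inf
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - sums[i] - sums[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
                elif abs(q - best_q) <= 1e-12 and best is not None:
                    cand = tuple(sorted((_pair_sort_key(nodes[i]), _pair_sort_key(nodes[j]))))
                    cur = tuple(
                        sorted((_pair_sort_key(nodes[best[0]]), _pair_sort_key(nodes[best[1]])))
                    )
                    if cand < cur:
                        best = (i, j)
        i, j = best  # type: ignore[misc]
        vi = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        # clamp negatives, moving the deficit to the sibling edge
        if vi < 0:
            vj += -vi
            vi = 0.0
        if vj < 0:
            vi += -vj
            vj = 0.0
        parent = TreeNode()
        nodes[i].length = float(vi)
        nodes[j].length = float(vj)
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j = active
    root = TreeNode()
    nodes[i].length = max(d[i, j], 0.0)
    nodes[j].length = 0.0
    root.extend([nodes[i], nodes[j]])
    return root


def build_marker_tree(records: Sequence[MarkerRecord], model: str = "K2P") -> TreeNode:
    """Distance tree over marker amplicons, leaves labelled
    ``marker_id|gene|species``."""
    if len(records) < 3:
        raise ValueError("need >= 3 sequences to build a tree")
    labels = [r.label for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate marker labels")
    dm = k2p_matrix([r.sequence for r in records], labels, model=model)
    return neighbor_joining(dm)
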