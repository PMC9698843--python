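"""Distance-based sanity tree over aligned proteins.

Bayesian inference over fungal-type TPPP alignments belongs to external
tools (the NEXUS writer emits a ready-to-edit template block for them); this
module provides the in-repo cross-check: p-distances under pairwise deletion
and canonical neighbor joining, which recovers the generating topology
exactly on additive (tree-metric) inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .seqio import ProteinSeq

GAP_CHARS = {"-", "."}


@dataclass
class DistanceMatrix:
    taxa: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and non-negative")


@dataclass
class PhyloTree:
    """An unrooted tree (trifurcating root node) with branch lengths."""

    root: TreeNode
    taxa: list
    negative_branches_clamped: bool = False

    def tip_distance(self, a: str, b: str) -> float:
        ta = self.root.find(a)
        tb = self.root.find(b)
        return float(ta.distance(tb))


def p_distance(
    msa: Sequence[ProteinSeq], gap_policy: str = "pairwise_deletion"
) -> DistanceMatrix:
    """Proportion of mismatched residues over comparable columns.

    Under ``pairwise_deletion`` (default) a column is skipped for a pair
    when either row has a gap there; ``complete_deletion`` drops columns
    with a gap in any row before comparing.
    """
    if gap_policy not in ("pairwise_deletion", "complete_deletion"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    if len(msa) < 2:
        raise ValueError("need at least two taxa")
    ncol = len(msa[0].seq)
    if any(len(r.seq) != ncol for r in msa):
        raise ValueError("alignment rows differ in length")
    rows = [r.seq for r in msa]
    if gap_policy == "complete_deletion":
        keep = [
            c for c in range(ncol)
            if all(row[c] not in GAP_CHARS for row in rows)
        ]
        rows = ["".join(row[c] for c in keep) for row in rows]
        ncol = len(keep)
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = 0
            mismatch = 0
            for a, b in zip(rows[i], rows[j]):
                if a in GAP_CHARS or b in GAP_CHARS:
                    continue
                comparable += 1
                if a != b:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {msa[i].id!r} and "
                    f"{msa[j].id!r}"
                )
            d[i, j] = d[j, i] = mismatch / comparable
    return DistanceMatrix([r.id for r in msa], d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor joining (Q-matrix criterion).

    Ties in the Q matrix break deterministically toward the earliest pair in
    current node order (input taxon order, then creation order of internal
    nodes). Negative branch-length estimates are clamped to zero and the
    tree is flagged.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=t) for t in dm.taxa]
    D = dm.d.astype(float).copy()
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        u = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = clamp(li)
        b.length = clamp(lj)
        u.extend([a, b])
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [u]
        D = newD

    # final trifurcation: three-point formulas
    root = TreeNode()
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, ln in zip(nodes, (la, lb, lc)):
        node.length = clamp(ln)
        root.append(node)
    return PhyloTree(root, list(dm.taxa), negative_branches_clamped=clamped)
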