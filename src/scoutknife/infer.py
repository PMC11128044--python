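"""Built-in desk-scale tree inference: Jukes-Cantor distances + neighbor
joining.

This backend exists so the full subsample-infer-consense pipeline runs
without external maximum-likelihood software; replicate supermatrices are
reduced to a single pairwise distance matrix (partitions ignored) and a
tree is built by the classical NJ agglomeration. Distances use pairwise
deletion: each pair is compared only over the sites where both taxa have a
non-gap residue, which keeps low-occupancy supermatrices usable.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np

from .seqio import GAP, SuperMatrix
from .trees import Clade, Tree

__all__ = ["DistanceMatrix", "jc_distance_matrix", "neighbor_joining", "D_MAX"]

# Distance assigned to saturated pairs (p >= 3/4) or pairs with no shared
# sites; substitutions per site.
D_MAX = 10.0


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distance")


def jc_distance_matrix(matrix: SuperMatrix) -> DistanceMatrix:
    """JC69 distances with pairwise deletion.

    p = mismatches / shared non-gap sites; d = -(3/4) ln(1 - 4p/3).
    Saturated pairs (p >= 0.75) and pairs sharing no sites get ``D_MAX``.
    """
    taxa = matrix.taxa
    if len(taxa) < 3:
        raise ValueError(f"need >= 3 taxa for distance inference, got {len(taxa)}")
    arr = np.frombuffer(
        "".join(matrix.seqs[t].upper() for t in taxa).encode("ascii"), dtype="S1"
    ).reshape(len(taxa), matrix.length)
    nongap = arr != GAP.encode()
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            m = int(shared.sum())
            if m == 0:
                dij = D_MAX
            else:
                p = float(np.sum((arr[i] != arr[j]) & shared)) / m
                dij = D_MAX if p >= 0.75 else -0.75 * log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(taxa=taxa, d=d)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining with the Q criterion.

    Deterministic: ties in Q are broken by the smallest (row, column)
    index pair; negative branch lengths are clamped to zero.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    nodes: list[Clade] = [Clade(name=t) for t in dm.taxa]
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin gives the smallest (row, col) pair on ties
        fi, fj = np.unravel_index(int(np.argmin(q)), q.shape)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = d[i, j]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2 * (m - 2))
        lj = dij - li
        parent = Clade()
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent.children = [nodes[i], nodes[j]]
        # new distances to remaining nodes
        new_row = np.zeros(d.shape[0] + 1)
        for fk in range(m):
            k = active[fk]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # join the final three around an unrooted central node
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    nodes[i].length = max(0.5 * (dij + dik - djk), 0.0)
    nodes[j].length = max(0.5 * (dij + djk - dik), 0.0)
    nodes[k].length = max(0.5 * (dik + djk - dij), 0.0)
    root = Clade(children=[nodes[i], nodes[j], nodes[k]])
    return Tree(root)
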