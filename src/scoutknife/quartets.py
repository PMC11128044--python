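"""Quartet status counts between two trees and the derived congruence
metrics.

For every 4-subset of the shared taxa, each tree induces one of the three
resolved quartet topologies (ab|cd, ac|bd, ad|bc) or leaves the quartet
unresolved (a star, from a polytomy). Comparing the two induced quartets
per subset yields the five-way status decomposition

    s   resolved identically in both trees
    d   resolved in both, differently
    r1  resolved only in tree 1
    r2  resolved only in tree 2
    u   unresolved in both

with s + d + r1 + r2 + u = Q = C(|shared taxa|, 4). All similarity and
divergence metrics reported here are ratios of these counts, so the raw
counts are always carried alongside the normalized values. Quartet-based
comparison is preferred over Robinson-Foulds here because consensus trees
deliberately retain polytomies, which bias RF.

Complexity is O(n^4) subsets times the number of splits — fine at the tens
of taxa this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, nan

from .trees import Tree, restrict_tree, tree_splits

__all__ = ["QuartetStatus", "quartet_status", "similarity_metrics", "METRIC_NAMES"]


@dataclass(frozen=True)
class QuartetStatus:
    Q: int
    s: int
    d: int
    r1: int
    r2: int
    u: int

    def __post_init__(self) -> None:
        if self.s + self.d + self.r1 + self.r2 + self.u != self.Q:
            raise ValueError("quartet status counts do not sum to Q")


def _split_membership(tree: Tree, index: dict[str, int]) -> list[list[bool]]:
    """Per split, a membership vector over the indexed taxa (True = side1)."""
    vectors = []
    for sp in tree_splits(tree):
        v = [False] * len(index)
        for t in sp.side1:
            v[index[t]] = True
        vectors.append(v)
    return vectors


def _resolve(vectors: list[list[bool]], a: int, b: int, c: int, d: int) -> int:
    """Induced quartet topology: 0 = ab|cd, 1 = ac|bd, 2 = ad|bc, 3 = star.

    Any split separating the four taxa 2+2 induces the resolution; all
    splits of one tree agree on it (they are pairwise compatible), so the
    first hit decides.
    """
    for v in vectors:
        va, vb, vc, vd = v[a], v[b], v[c], v[d]
        if va == vb and vc == vd and va != vc:
            return 0
        if va == vc and vb == vd and va != vb:
            return 1
        if va == vd and vb == vc and va != vb:
            return 2
    return 3


def quartet_status(tree1: Tree, tree2: Tree) -> QuartetStatus:
    """Status counts over all 4-subsets of the shared taxon set.

    Both trees are first restricted to their shared taxa, so trees over
    different leaf sets (e.g. consensus trees that dropped low-occupancy
    taxa) compare cleanly.
    """
    shared = tree1.taxa & tree2.taxa
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared taxa (need >= 4)")
    t1 = restrict_tree(tree1, shared) if tree1.taxa != shared else tree1
    t2 = restrict_tree(tree2, shared) if tree2.taxa != shared else tree2
    taxa = sorted(shared)
    index = {t: i for i, t in enumerate(taxa)}
    v1 = _split_membership(t1, index)
    v2 = _split_membership(t2, index)

    s = d = r1 = r2 = u = 0
    for a, b, c, dd in combinations(range(len(taxa)), 4):
        q1 = _resolve(v1, a, b, c, dd)
        q2 = _resolve(v2, a, b, c, dd)
        if q1 == 3 and q2 == 3:
            u += 1
        elif q2 == 3:
            r1 += 1
        elif q1 == 3:
            r2 += 1
        elif q1 == q2:
            s += 1
        else:
            d += 1
    return QuartetStatus(Q=comb(len(taxa), 4), s=s, d=d, r1=r1, r2=r2, u=u)


METRIC_NAMES = (
    "do_not_conflict",
    "explicitly_agree",
    "strict_joint_assertions",
    "semi_strict_joint_assertions",
    "quartet_divergence",
    "quartet_similarity",
    "symmetric_difference_similarity",
    "marczewski_steinhaus_similarity",
    "steel_penny_similarity",
)


def _ratio(num: float, den: float) -> float:
    return num / den if den else nan


def similarity_metrics(status: QuartetStatus) -> dict[str, float]:
    """The named congruence metrics derived from one status decomposition.

    Values are in [0, 1] where defined; a zero-denominator ratio is
    reported as NaN (never as 0). ``quartet_similarity`` is
    1 - quartet_divergence and doubles as the "overall similarity"
    summary.
    """
    if status.Q < 1:
        raise ValueError("Q must be >= 1")
    Q, s, d, r1, r2, u = (
        status.Q, status.s, status.d, status.r1, status.r2, status.u,
    )
    divergence = (2 * d + r1 + r2) / (2 * Q)
    return {
        "do_not_conflict": (s + r1 + r2 + u) / Q,
        "explicitly_agree": s / Q,
        "strict_joint_assertions": _ratio(s, s + d),
        "semi_strict_joint_assertions": _ratio(s, s + d + u),
        "quartet_divergence": divergence,
        "quartet_similarity": 1.0 - divergence,
        "symmetric_difference_similarity": 1.0
        - _ratio(2 * d + r1 + r2, 2 * s + 2 * d + r1 + r2),
        "marczewski_steinhaus_similarity": _ratio(s, s + 2 * d + r1 + r2),
        "steel_penny_similarity": (s + u) / Q,
    }
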