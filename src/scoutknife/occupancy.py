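"""Per-taxon gene occupancy and the exact hypergeometric sampling model.

A replicate draws ``n`` genes without replacement from the ``N`` genes of
the source dataset. For a taxon present in ``K`` of those genes, the number
of sampled genes that contain it is hypergeometric:

    P(X = k) = C(K, k) * C(N - K, n - k) / C(N, n)

Low-occupancy taxa are the binding constraint on the subsampling design:
a taxon found in few genes may be entirely absent from some replicates,
and the expected number of carrier genes per replicate is n*K/N. The
calculator here answers the two design questions that matter before a run:
how well represented is each taxon expected to be at a given sample size,
and how large must the sample be so that every replicate almost surely
contains the rarest taxon at all (:func:`auto_sample_size`).

All probabilities are computed with exact integer binomials (converted to
float only on output), so printed values are correct to every displayed
digit rather than to floating-point approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

from .seqio import GeneAlignment

__all__ = [
    "OccupancyProfile",
    "HypergeomSpec",
    "occupancy_profile",
    "hypergeom_pmf",
    "prob_at_most",
    "prob_at_least",
    "expected_count",
    "auto_sample_size",
]


@dataclass(frozen=True)
class OccupancyProfile:
    """Gene counts per taxon: K[t] of N genes contain taxon t."""

    N: int
    K: dict[str, int]

    def __post_init__(self) -> None:
        for t, k in self.K.items():
            if not 0 <= k <= self.N:
                raise ValueError(f"taxon {t!r}: K={k} outside [0, N={self.N}]")

    @property
    def mean_occupancy(self) -> float:
        return sum(self.K.values()) / (self.N * len(self.K))

    def min_taxon(self) -> tuple[str, int]:
        """The taxon present in the fewest genes (ties: lexicographic)."""
        return min(self.K.items(), key=lambda kv: (kv[1], kv[0]))


@dataclass(frozen=True)
class HypergeomSpec:
    """Population of N genes, K of which contain the focal taxon; sample n."""

    N: int
    K: int
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.K <= self.N:
            raise ValueError(f"K={self.K} outside [0, N={self.N}]")
        if not 1 <= self.n <= self.N:
            raise ValueError(f"n={self.n} outside [1, N={self.N}]")


def occupancy_profile(genes: list[GeneAlignment]) -> OccupancyProfile:
    """Count, per taxon, the genes in which it has >=1 non-gap residue."""
    if not genes:
        raise ValueError("occupancy profile of an empty gene list")
    counts: dict[str, int] = {}
    for g in genes:
        for t in g.taxa:
            counts.setdefault(t, 0)
            if g.has_data(t):
                counts[t] += 1
    return OccupancyProfile(N=len(genes), K=counts)


def _pmf_fraction(spec: HypergeomSpec, k: int) -> Fraction:
    if not 0 <= k <= spec.n:
        raise ValueError(f"k={k} outside [0, n={spec.n}]")
    if k > spec.K or spec.n - k > spec.N - spec.K:
        return Fraction(0)
    return Fraction(
        comb(spec.K, k) * comb(spec.N - spec.K, spec.n - k),
        comb(spec.N, spec.n),
    )


def hypergeom_pmf(spec: HypergeomSpec, k: int) -> float:
    """Exact P(X = k) for the number of carrier genes in one replicate."""
    return float(_pmf_fraction(spec, k))


def prob_at_most(spec: HypergeomSpec, k: int) -> float:
    """Exact P(X <= k)."""
    if not 0 <= k <= spec.n:
        raise ValueError(f"k={k} outside [0, n={spec.n}]")
    return float(sum(_pmf_fraction(spec, j) for j in range(k + 1)))


def prob_at_least(spec: HypergeomSpec, k: int) -> float:
    """Exact P(X >= k) = 1 - P(X <= k-1)."""
    if not 0 <= k <= spec.n:
        raise ValueError(f"k={k} outside [0, n={spec.n}]")
    tail = Fraction(1) - sum(_pmf_fraction(spec, j) for j in range(k))
    return float(tail)


def expected_count(spec: HypergeomSpec) -> float:
    """E[X] = n*K/N: expected carrier genes per replicate."""
    return spec.n * spec.K / spec.N


def auto_sample_size(N: int, K_min: int, target: float = 0.999) -> int:
    """Smallest sample size n whose replicates almost surely carry the
    rarest taxon.

    Returns the minimal n with P(X >= 1) >= target when the rarest taxon
    sits in K_min of the N genes. P(X = 0) = C(N-K_min, n) / C(N, n), which
    is strictly decreasing in n and hits 0 at n = N - K_min + 1, so a
    solution always exists.
    """
    if not 1 <= K_min <= N:
        raise ValueError(f"K_min={K_min} outside [1, N={N}]")
    if not 0 < target < 1:
        raise ValueError(f"target={target} outside (0, 1)")
    denom_pool = N - K_min
    for n in range(1, N + 1):
        if n > denom_pool:
            return n  # more draws than non-carriers: certainty
        p_zero = Fraction(comb(denom_pool, n), comb(N, n))
        if 1 - p_zero >= target:
            return n
    return N  # unreachable; n = N always gives P = 1 when K_min >= 1
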