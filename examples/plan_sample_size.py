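"""Size a gene-jackknife analysis around its rarest taxon.

A taxon present in only 98 of 1049 genes constrains how informative
100-gene subsamples can be. The exact hypergeometric model answers the
design questions before any tree is inferred.
"""

from scoutknife import (
    HypergeomSpec,
    auto_sample_size,
    expected_count,
    hypergeom_pmf,
    prob_at_least,
)

N, K = 1049, 98  # genes in the dataset / genes containing the rare taxon

for n in (50, 100, 200):
    spec = HypergeomSpec(N=N, K=K, n=n)
    print(f"sample size n = {n}:")
    print(f"  expected carrier genes per sample : {expected_count(spec):.1f}")
    print(f"  P(sample has >= 9 carriers)       : {100 * prob_at_least(spec, 9):.2f}%")
    print(f"  P(sample has >= 1 carrier)        : {100 * prob_at_least(spec, 1):.4f}%")
    print(f"  P(sample has no carrier at all)   : {100 * hypergeom_pmf(spec, 0):.2f}%")

n_auto = auto_sample_size(N, K, target=0.999)
print(f"\nsmallest n giving every sample a 99.9% chance of >= 1 carrier: {n_auto}")

# Reading: at n=100 the rare taxon is virtually always present (>99.99%),
# but only ~60% of samples carry the ~9 genes a proportional share implies;
# halving to n=50 leaves ~0.65% of samples with no information on it at all.
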