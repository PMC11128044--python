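# scoutknife

Gene-jackknife robustness for phylogenomic datasets: draw many small
random multi-gene subsamples from a large gene pool, infer one tree per
subsample, and read topological support straight off the consensus —
together with the exact hypergeometric calculator that sizes the samples
around low-occupancy taxa, and the quartet congruence metrics used to
evaluate the result.

## The problem

With genome-scale datasets of thousands of genes, branch support no
longer has to come from pseudo-replicating alignment sites (the classical
bootstrap). The data pool is large enough to sample *real* replicates:
datasets of `n` genes drawn uniformly without replacement from the `N`
available genes, repeated `R` times. A gene can never appear twice in one
replicate but may recur across replicates. Each replicate yields a tree;
the frequency with which a bipartition appears across the `R` trees is
its support, and the consensus tree at a threshold (0.5 majority, 0.7
conservative, or sub-majority plurality) is simultaneously the
phylogenetic estimate and its robustness assessment. Conflict among genes
— whether biological or methodological — shows up honestly as polytomies
and depressed support rather than being filtered away by gene selection.

Two quantitative companions make the approach usable in practice:

* **Occupancy design.** A taxon present in `K` of the `N` genes appears in
  a replicate's sample `X ~ Hypergeometric(N, K, n)` times:
  `P(X = k) = C(K,k)·C(N−K,n−k)/C(N,n)`, with expectation `nK/N`. The
  calculator answers how well any taxon is represented at a given `n`,
  and `auto_sample_size` returns the smallest `n` at which every
  replicate contains the rarest taxon with 99.9% probability. All
  probabilities are computed with exact integer arithmetic.
* **Quartet congruence.** Trees are compared by classifying every
  4-taxon subset as resolved identically (`s`), differently (`d`), in
  only one tree (`r1`, `r2`) or in neither (`u`), and deriving the named
  metrics (do-not-conflict, explicit agreement, strict/semi-strict joint
  assertions, quartet divergence/similarity, symmetric difference,
  Marczewski–Steinhaus, Steel–Penny). Quartets handle the polytomies a
  conservative consensus deliberately retains, which bias
  Robinson–Foulds distances.

A built-in Jukes–Cantor + neighbor-joining backend lets the whole
pipeline run at desk scale without external software; for real analyses
the package emits ready-to-run command lines for an external
maximum-likelihood tool instead, and a seeded simulator generates
multi-gene datasets with a known species tree, a controllable fraction of
discordant gene trees, and per-taxon occupancy dropout for validation.

## Worked example: sizing samples around a rare taxon

A taxon present in only 98 of 1049 genes (`examples/plan_sample_size.py`):

```
sample size n = 100:
  expected carrier genes per sample : 9.3
  P(sample has >= 9 carriers)       : 60.52%
  P(sample has >= 1 carrier)        : 99.9967%
  P(sample has no carrier at all)   : 0.00%

smallest n giving every sample a 99.9% chance of >= 1 carrier: 69
```

At `n = 100` the rare taxon is virtually always present, but only 60.52%
of samples carry the ≥ 9 carrier genes a proportional share implies; at
`n = 50` about 0.65% of samples would contain no information about the
taxon at all. Doubling to `n = 200` raises the ≥ 9-carrier chance to
99.85%.

The same from the command line:

```bash
scoutknife plan --N 1049 --K 98 --n 100 --at-least 9
scoutknife auto --N 1049 --K 98          # -> n = 69
```

## Worked example: full pipeline on simulated data

`examples/simulate_and_run.py` simulates 60 clean genes on an 8-taxon
species tree, subsamples 30-gene replicates 100 times, infers each
replicate tree with the built-in JC+NJ backend and prints:

```
consensus at 0.5: (A,B,((C,D)1.0000,(((E,F)1.0000,G)1.0000,H)1.0000)1.0000);
  topology identical to species tree: True
consensus at 0.7: (A,B,((C,D)1.0000,(((E,F)1.0000,G)1.0000,H)1.0000)1.0000);
  topology identical to species tree: True
explicit agreement with species tree : 100.00%
quartet divergence                   : 0.00%
```

Internal-node labels are jackknife supports: the fraction of replicate
trees displaying that branch. With discordant gene trees
(`examples/discordance_support.py`), the support of the perturbed branch
estimates the concordant-gene fraction `1 − π`:

```
pi    expected  observed support
0.10  0.90      0.890
0.30  0.70      0.688
0.45  0.55      0.548
```

## Command-line interface

`scoutknife` is a thin wrapper over the library: `occupancy`, `plan`,
`auto` (design), `sample`, `commands` (replicates and external command
emission), `infer`, `consensus`, `compare` (trees and metrics),
`simulate`, and `run` (the end-to-end pipeline with a TOML config,
writing `manifest.tsv`, `treelist.nwk`, `consensus_t*.nwk`,
`occupancy.tsv`, `metrics.tsv` and a resolved-config echo). Identical
config and seed reproduce byte-identical artifacts.

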