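# Methods

## The subsampling model

The unit of resampling is the gene, not the alignment site. From `N`
source genes, each replicate draws `n` genes uniformly **without
replacement** (no gene twice in one replicate); the `R` replicates are
mutually independent, so a gene may recur across replicates. Defaults are
`n = 100`, `R = 100`. Each replicate's genes are concatenated into a
supermatrix over the union of their taxa — a taxon absent from a sampled
gene is padded with `-` over that gene's columns, and a taxon absent from
every sampled gene is absent from the replicate entirely. One tree is
inferred per replicate, and the support of a bipartition is its frequency
across the replicate trees. Because replicates are genuine subsets of the
data rather than pseudo-replicates of sites, support reflects how evenly
the genome supports a branch; gene-tree conflict surfaces as depressed
support and, in the consensus, as polytomies.

Sampling uses a partial Fisher–Yates shuffle on a per-replicate RNG
substream seeded from `(seed, replicate_id)` (PCG64 via
`numpy.random.SeedSequence`). Consequences: manifests are reproducible
bit-for-bit across platforms, and extending a run from `R` to `R' > R`
replicates never changes the first `R`. Gene order within a replicate is
the draw order; it affects only partition layout, not topology.

## Occupancy and the hypergeometric design rule

For a taxon found in `K` of the `N` genes, the number of carrier genes in
one replicate is exactly `Hypergeometric(N, K, n)`. The calculator
(`occupancy` module) evaluates pmf and tail probabilities with exact
integer binomials (`math.comb` under `fractions.Fraction`), converting to
float only on output, so printed percentages are exact at any displayed
precision rather than inherited from floating-point error. A taxon counts
as present in a gene when it has at least one non-gap residue there.

`auto_sample_size(N, K_min, target=0.999)` returns the smallest `n` such
that `P(X ≥ 1) ≥ target` for the minimum-occupancy taxon. `P(X = 0) =
C(N−K,n)/C(N,n)` is strictly decreasing in `n` and reaches 0 at
`n = N−K+1`, so the minimal `n` is found by direct scan. The target
applies to per-taxon representation (at least one gene containing the
rarest taxon per replicate), which is the quantity that bounds the
method's effective power. The pipeline warns for every taxon whose
probability of being entirely absent from a replicate exceeds 1%.

## Consensus with variable leaf sets

Support counting uses informative-tree denominators so that replicates
missing a low-occupancy taxon still vote on the splits they can see: for
a candidate bipartition `S` of the taxon universe and a tree with leaf
set `L`, the tree is *informative* iff both sides of `S ∩ L` retain ≥ 2
taxa, and *supports* `S` iff that restriction is one of the tree's own
splits. The frequency is supporting / informative.

Candidates are harvested from the trees themselves. A split of a tree
covering the full universe is its own candidate. A split of a partial
tree is lifted to the universe by grouping the missing taxa with the side
containing the lexicographically smallest taxon present in that tree — a
deterministic convention needed only to give partial splits a canonical
universe identity; the vote counting that follows uses exact restriction,
so every reported frequency is exact regardless of the lifting choice.
With uniform leaf sets (the overwhelmingly common case) the machinery
reduces to the classical bipartition table.

Consensus is greedy: candidates are ranked by (frequency descending,
canonical split encoding ascending), and a split is accepted when its
frequency meets the threshold (comparison is `≥`, so a split at exactly
the threshold is kept) and it is compatible — by the four-intersection
test — with everything already accepted. For thresholds above 0.5 this
coincides with plain majority-threshold consensus, since conflicting
splits cannot both exceed 50% of informative trees; below 0.5 it is a
plurality consensus with a deterministic lexicographic tie-break. The
accepted splits, being pairwise compatible, form a laminar cluster family
when rooted at the smallest taxon; the consensus tree is assembled by
nesting those clusters, each edge labelled with its frequency (4 decimals
in Newick output). Consensus trees carry supports only, no branch
lengths.

## Quartet congruence

Two trees are compared on their shared taxon set (each restricted first,
suppressing degree-2 vertices). For each of the `Q = C(m, 4)` subsets the
induced quartet in a tree is found by scanning the tree's splits for one
that separates the four taxa 2+2 — all splits of one tree agree on a
quartet's resolution, so the first hit decides; no separating split means
the quartet is unresolved (a polytomy). The five-way status `(s, d, r1,
r2, u)` then yields:

| metric | formula |
|---|---|
| do_not_conflict | (s+r1+r2+u)/Q |
| explicitly_agree | s/Q |
| strict_joint_assertions | s/(s+d) |
| semi_strict_joint_assertions | s/(s+d+u) |
| quartet_divergence | (2d+r1+r2)/(2Q) |
| quartet_similarity | 1 − quartet_divergence |
| symmetric_difference_similarity | 1 − (2d+r1+r2)/(2s+2d+r1+r2) |
| marczewski_steinhaus_similarity | s/(s+2d+r1+r2) |
| steel_penny_similarity | (s+u)/Q |

These formulas are this package's pinned conventions for the named
metrics; the raw counts are always emitted alongside so any alternative
normalization can be recomputed. Zero-denominator ratios are reported as
NaN, never as 0. `quartet_similarity` doubles as the overall-similarity
summary. The enumeration is O(n⁴ · splits), fine for the tens of taxa
this package targets; no sub-quartic algorithm is attempted.

## Built-in inference backend

The JC69 + neighbor-joining backend exists to exercise the subsampling
machinery end-to-end at desk scale, not as a substitute for
maximum-likelihood inference on real data (the `external-commands`
backend writes per-replicate alignments, partition files and shell
command lines for that). Distances use pairwise deletion — each pair is
compared over the sites where both have non-gap residues — because
complete deletion would leave low-occupancy supermatrices without usable
columns. `p ≥ 0.75` (saturation) or zero shared sites maps to a ceiling
distance of 10 substitutions/site. NJ uses the standard Q-criterion with
ties broken by the smallest (row, column) index pair and negative branch
lengths clamped to zero, making output deterministic. Partition
structure is ignored by this backend (one concatenated distance matrix);
per-gene models are reachable only through the external command path.

## The simulator

The generator emulates the structure a gene-jackknife study must cope
with, with every knob explicit:

* **Species tree**: user-supplied, with branch lengths in
  substitutions/site.
* **Discordance**: each gene tree independently equals the species tree
  with probability `1 − π`, or is rewired by one uniformly chosen
  nearest-neighbor interchange at a designated focal internal edge. This
  makes `1 − π` the analytically known target for the focal branch's
  consensus support. It is a one-parameter caricature of gene-tree
  conflict: it does *not* model incomplete lineage sorting, so
  coalescent-driven patterns (anomalous gene trees, branch-length
  dependence of discordance) are outside what passing tests demonstrate.
* **Sequences**: i.i.d. sites under JC69 (uniform root base, per-branch
  change probability `(3/4)(1 − e^{−4t/3})`), gene lengths uniform over
  a range (default 200–600 sites; the validation studies use 300–500).
  No rate heterogeneity, no amino-acid models, no empirical "mimicry" of
  real gene alignments.
* **Occupancy**: each taxon is dropped from each gene independently with
  probability `1 − occupancy[taxon]`, reproducing regimes like a taxon
  present in 98 of 1049 genes. Missingness is uncorrelated across taxa
  and genes; block-structured missingness of real datasets is not
  modeled. A gene left with < 4 taxa is re-drawn (100 attempts, then an
  error).

All simulation randomness derives from one seed via named substreams.

## Validation study sizes

The shipped studies were sized to be decisive yet quick: oracle
equivalence sweeps every hypergeometric case up to `N = 12` against
exhaustive subset enumeration, 200 random 8-taxon tree pairs against a
four-point path-length quartet oracle, and consensus supports against
brute-force counts over all bipartitions of ≤ 8-taxon universes; NJ
consistency uses 500 random additive matrices of 5–10 taxa (recovery is
exact, as theory requires); discordance recovery uses a 12-taxon tree
with 1049 gene trees, `n = 100`, `R = 100`, five seeds per
π ∈ {0.1, 0.3, 0.45} with an acceptance band of ±0.15 around `1 − π`;
the end-to-end check uses 8 taxa, 60 genes of 300–500 bp and 100
replicates of 30 genes. In the discordance study the true gene trees are
fed directly to the subsampler (the pooled trees of all sampled genes
form the treelist), isolating sampling + consensus from sequence-level
inference error.

## Numerical and design choices

* Gap/pad character is `-`; `?` is not treated specially.
* Partition files use the RAxML-style 1-based inclusive dialect
  (`DNA, gene = start-end`); internally coordinates are 0-based
  half-open. The model token is optional on read.
* Taxon names containing Newick-reserved characters (`,():;[]'` or
  whitespace) are rejected at parse time rather than silently sanitized;
  FASTA headers are truncated at the first whitespace.
* Internal node labels in Newick input are read as supports when numeric
  in [0, 1], otherwise kept as names.
* Consensus consumes every replicate tree (burn-in 0, sampling rate 1).
* Replicate-level inference failures are only possible in the external
  backend; when re-importing such results, `scoutknife consensus
  --expected-replicates R` refuses to summarize a treelist holding fewer
  than 90% of the planned trees (failed replicates are simply absent and
  thus excluded from the denominator).
* Sequences are treated as opaque residue strings everywhere except the
  distance and simulation modules, which assume nucleotides.

## Known limitations

* The NNI discordance model concentrates conflict at one edge; real
  datasets spread it over many, and the per-edge support targets are then
  not independent.
* The built-in backend's model mismatch (JC on possibly non-JC data) is
  irrelevant for the clean-simulation checks but means its trees should
  never be interpreted as a real analysis.
* Quartet metrics are reported on quartets; node-proportion analogues of
  "agreement"/"conflict" percentages are not computed, and values are
  labelled accordingly in output.
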