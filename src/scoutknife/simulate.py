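"""Synthetic multi-gene datasets with a known species tree, controllable
gene-tree discordance, per-taxon occupancy dropout, and JC sequence
evolution.

The generator produces the structure a gene-jackknife study needs to
validate against: ``n_genes`` gene trees, each equal to the species tree
with probability 1 - pi and otherwise rewired by one nearest-neighbor
interchange (NNI) at a designated focal internal edge. The fraction pi of
discordant genes is then the analytically known target: the focal
bipartition should appear in a fraction ~(1 - pi) of gene trees, and a
majority consensus over jackknife replicates should recover it with
support close to 1 - pi. Occupancy is modeled as i.i.d. per-taxon,
per-gene dropout, reproducing the low-occupancy regimes (a taxon present
in only, say, 98 of 1049 genes) that drive the hypergeometric sample-size
analysis.

Discordance via a single NNI edge rather than coalescent simulation is a
deliberate choice: it gives a one-parameter, analytically tractable
discordance structure. It does not emulate incomplete lineage sorting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import GeneAlignment
from .trees import Clade, Split, Tree, tree_splits

__all__ = [
    "SimulationSpec",
    "internal_edges",
    "simulate_gene_trees",
    "evolve_jc",
    "simulate_dataset",
    "nni_neighbors",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic multi-gene dataset.

    occupancy maps taxon -> retention probability in (0, 1]; taxa not
    listed default to 1 (always present). Branch lengths of the species
    tree are in substitutions per site.
    """

    species_tree: Tree
    n_genes: int = 1049
    discordance_pi: float = 0.0
    focal_edge: int | str = "random"
    occupancy: dict[str, float] = field(default_factory=dict)
    length_range: tuple[int, int] = (200, 600)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.discordance_pi <= 1.0:
            raise ValueError("discordance_pi outside [0, 1]")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad length_range {self.length_range}")
        for t, p in self.occupancy.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"occupancy[{t!r}]={p} outside (0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def internal_edges(tree: Tree) -> list[Split]:
    """The internal edges of a tree as splits, in canonical sorted order."""
    return sorted(tree_splits(tree), key=lambda s: s.key())


def _find_edge_node(tree: Tree, split: Split) -> tuple[Clade, Clade]:
    """(parent, child) pair whose edge induces *split* in the rooted form."""
    universe = tree.taxa

    def walk(node: Clade, parent: Clade | None):
        below = frozenset()
        for c in node.children:
            sub = walk(c, node)
            if isinstance(sub, tuple):
                return sub
            below |= sub
        if node.is_leaf():
            return frozenset([node.name])
        if parent is not None and len(below) >= 2 and len(universe - below) >= 2:
            if Split(below, universe - below) == split:
                return (parent, node)
        return below

    hit = walk(tree.root, None)
    if not isinstance(hit, tuple):
        raise ValueError(f"no internal edge induces split {split!r}")
    return hit


def nni_neighbors(tree: Tree, edge: Split) -> tuple[Tree, Tree]:
    """The two nearest-neighbor-interchange rearrangements at an edge.

    The focal edge separates subtrees (A, B) on the child side from the
    rest; swapping one child-side subtree with one parent-side subtree
    yields the two alternative resolutions AC|BD and AD|BC.
    """
    out = []
    for which in (0, 1):
        t = tree.copy()
        parent, child = _find_edge_node(t, edge)
        if len(child.children) != 2:
            raise ValueError("NNI requires a binary resolution at the focal edge")
        sibling = next(c for c in parent.children if c is not child)
        swap = child.children[which]
        parent.children[parent.children.index(sibling)] = swap
        child.children[which] = sibling
        out.append(Tree(t.root))
    return out[0], out[1]


def simulate_gene_trees(spec: SimulationSpec) -> list[Tree]:
    """Per gene: the species tree, or (with probability pi) one uniformly
    chosen NNI neighbor at the focal edge."""
    edges = internal_edges(spec.species_tree)
    if not edges:
        raise ValueError("species tree has no internal edges")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((spec.seed, 0))))
    if spec.focal_edge == "random":
        focal = edges[int(rng.integers(len(edges)))]
    else:
        if not 0 <= int(spec.focal_edge) < len(edges):
            raise ValueError(
                f"focal_edge {spec.focal_edge} is not an internal edge index "
                f"(tree has {len(edges)})"
            )
        focal = edges[int(spec.focal_edge)]
    alt1, alt2 = nni_neighbors(spec.species_tree, focal)
    out = []
    for _ in range(spec.n_genes):
        if rng.random() < spec.discordance_pi:
            out.append((alt1 if rng.random() < 0.5 else alt2).copy())
        else:
            out.append(spec.species_tree.copy())
    return out


def focal_split(spec: SimulationSpec) -> Split:
    """The split whose support the discordance parameter targets."""
    edges = internal_edges(spec.species_tree)
    if spec.focal_edge == "random":
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((spec.seed, 0))))
        return edges[int(rng.integers(len(edges)))]
    return edges[int(spec.focal_edge)]


def evolve_jc(tree: Tree, n_sites: int, seed: int) -> GeneAlignment:
    """Evolve i.i.d. sites along a tree under JC69.

    Uniform root base; on a branch of length t (substitutions/site) each
    site changes to each alternative base with probability
    (1/4)(1 - e^{-4t/3}). Every branch must carry a length.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    root_states = rng.integers(4, size=n_sites)
    seqs: dict[str, str] = {}

    def descend(node: Clade, states: np.ndarray) -> None:
        for child in node.children:
            if child.length is None:
                raise ValueError(
                    f"branch above {child.name or 'an internal node'} has no length"
                )
            p_change = 0.75 * (1.0 - np.exp(-4.0 * child.length / 3.0))
            mutate = rng.random(n_sites) < p_change
            child_states = states.copy()
            if mutate.any():
                # a changed site moves to one of the 3 other bases uniformly
                shift = rng.integers(1, 4, size=int(mutate.sum()))
                child_states[mutate] = (child_states[mutate] + shift) % 4
            if child.is_leaf():
                seqs[child.name] = _BASES[child_states].tobytes().decode("ascii")
            else:
                descend(child, child_states)

    descend(tree.root, root_states)
    gene = GeneAlignment(gene_id="simulated", seqs=seqs)
    return gene


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[list[GeneAlignment], list[Tree]]:
    """Generate gene alignments plus the true gene trees.

    Per gene: draw the gene tree, a uniform length from ``length_range``,
    evolve sequences, then drop each taxon independently with probability
    1 - occupancy[taxon]. A gene left with < 4 taxa is re-drawn (the
    dropout only, bounded retries).
    """
    gene_trees = simulate_gene_trees(spec)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((spec.seed, 1))))
    lo, hi = spec.length_range
    width = len(str(spec.n_genes))
    alignments = []
    for i, gtree in enumerate(gene_trees):
        n_sites = int(rng.integers(lo, hi + 1))
        aln = evolve_jc(gtree, n_sites, seed=int(rng.integers(2**31)))
        taxa = list(aln.seqs)
        kept = None
        for _attempt in range(100):
            trial = [
                t for t in taxa
                if rng.random() < spec.occupancy.get(t, 1.0)
            ]
            if len(trial) >= 4:
                kept = trial
                break
        if kept is None:
            raise RuntimeError(
                f"gene {i + 1}: occupancy dropout left < 4 taxa in 100 draws; "
                "occupancy probabilities are too low"
            )
        gene_id = f"gene{i + 1:0{width}d}"
        alignments.append(
            GeneAlignment(gene_id=gene_id, seqs={t: aln.seqs[t] for t in kept})
        )
    return alignments, gene_trees
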