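"""Shared fixtures and independent oracle helpers.

The helpers here deliberately avoid the package's own tree machinery:
random trees are built as nested tuples with splits and path lengths
computed by direct recursion, so they can serve as independent references
for neighbor joining, split extraction and quartet counting.
"""

from __future__ import annotations

import random

import pytest

from scoutknife import seqio
from scoutknife.trees import parse_newick

# ---------------------------------------------------------------------------
# independent random-tree generator (nested tuples, no package code)
# ---------------------------------------------------------------------------


def random_tuple_tree(rng: random.Random, taxa: list[str], bl_lo=0.05, bl_hi=1.0):
    """Random binary tree by random pairwise joining.

    Every element is a (subtree, branch_length) pair; a subtree is either a
    leaf name or a (left, right) tuple of elements.
    """

    def wrap(x):
        return (x, rng.uniform(bl_lo, bl_hi))

    nodes = [wrap(t) for t in taxa]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(wrap((a, b)))
    return nodes[0]


def tuple_tree_leaves(node) -> frozenset[str]:
    sub, _bl = node
    if isinstance(sub, str):
        return frozenset([sub])
    return tuple_tree_leaves(sub[0]) | tuple_tree_leaves(sub[1])


def tuple_tree_splits(node) -> set[frozenset[frozenset[str]]]:
    """Nontrivial bipartitions of the unrooted tree, as unordered side pairs."""
    universe = tuple_tree_leaves(node)
    out = set()

    def walk(nd):
        sub, _bl = nd
        if isinstance(sub, str):
            return
        for child in sub:
            below = tuple_tree_leaves(child)
            rest = universe - below
            if len(below) >= 2 and len(rest) >= 2:
                out.add(frozenset([below, rest]))
            walk(child)

    walk(node)
    return out


def tuple_tree_distances(node) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths by direct recursion."""
    dist: dict[tuple[str, str], float] = {}

    def depths(nd) -> dict[str, float]:
        sub, bl = nd
        if isinstance(sub, str):
            return {sub: bl}
        left = depths(sub[0])
        right = depths(sub[1])
        for a, da in left.items():
            for b, db in right.items():
                key = (a, b) if a < b else (b, a)
                dist[key] = da + db
        merged = {t: d + bl for t, d in {**left, **right}.items()}
        return merged

    sub, _ = node
    if isinstance(sub, str):
        return {}
    # root: combine its two children without the root's own branch
    left = depths(sub[0])
    right = depths(sub[1])
    # cross-root pairs; within-side pairs were recorded during recursion
    for a, da in left.items():
        for b, db in right.items():
            key = (a, b) if a < b else (b, a)
            dist[key] = da + db
    return dist


def tuple_tree_newick(node) -> str:
    def render(nd):
        sub, bl = nd
        if isinstance(sub, str):
            return f"{sub}:{bl:.6f}"
        return f"({render(sub[0])},{render(sub[1])}):{bl:.6f}"

    sub, _ = node
    if isinstance(sub, str):
        raise ValueError("single-leaf tree")
    return f"({render(sub[0])},{render(sub[1])});"


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def two_genes():
    """The canonical 2-gene concatenation example: g2 lacks taxon C."""
    g1 = seqio.GeneAlignment("g1", {"A": "ACGT", "B": "ACGA", "C": "ACGC"})
    g2 = seqio.GeneAlignment("g2", {"A": "TTTT", "B": "TTTA"})
    return [g1, g2]


@pytest.fixture(scope="session")
def species12():
    """A 12-taxon binary species tree with internal branches of 0.05."""
    nwk = (
        "(((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05):0.05,"
        "(((E:0.1,F:0.1):0.05,(G:0.1,H:0.1):0.05):0.05,"
        "((I:0.1,J:0.1):0.05,K:0.1):0.05):0.05,L:0.1);"
    )
    return parse_newick(nwk)


@pytest.fixture(scope="session")
def species8():
    """An 8-taxon binary species tree, internal branches >= 0.05."""
    nwk = (
        "(((A:0.1,B:0.1):0.08,(C:0.1,D:0.1):0.08):0.08,"
        "((E:0.1,F:0.1):0.08,G:0.1):0.08,H:0.1);"
    )
    return parse_newick(nwk)


@pytest.fixture(scope="session")
def clean_sim_dataset(species8):
    """60 genes, 8 taxa, no discordance, full occupancy, 300-500 bp."""
    from scoutknife.simulate import SimulationSpec, simulate_dataset

    spec = SimulationSpec(
        species_tree=species8,
        n_genes=60,
        discordance_pi=0.0,
        focal_edge=0,
        length_range=(300, 500),
        seed=2024,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def clean_genes_dir(tmp_path_factory, clean_sim_dataset):
    genes, _trues = clean_sim_dataset
    d = tmp_path_factory.mktemp("genes")
    for g in genes:
        seqio.write_fasta(g, d / f"{g.gene_id}.fasta")
    return d
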