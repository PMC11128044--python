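"""Unrooted tree topologies, bipartitions, split frequencies over treelists
with variable leaf sets, and threshold/greedy consensus trees.

The consensus machinery is the heart of the subsampling method: each
replicate contributes one tree, and an internal branch of the consensus is
retained when the fraction of replicate trees displaying its bipartition
meets the chosen threshold (0.5 majority, 0.7 conservative, or sub-majority
plurality). Because low-occupancy taxa can be entirely absent from some
replicates, frequencies are computed with informative-tree denominators: a
tree votes on a split only if at least two taxa of each side are present in
that tree's leaf set.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

__all__ = [
    "Clade",
    "Tree",
    "Split",
    "SplitFrequencies",
    "parse_newick",
    "write_newick",
    "read_treelist",
    "write_treelist",
    "tree_splits",
    "split_frequencies",
    "consensus_tree",
    "splits_compatible",
    "tree_from_splits",
    "restrict_tree",
]


class NewickError(ValueError):
    """Malformed Newick input."""


@dataclass
class Clade:
    """A node of a (rooted representation of an) unrooted tree."""

    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def iter_nodes(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def copy(self) -> "Clade":
        return Clade(
            name=self.name,
            length=self.length,
            support=self.support,
            children=[c.copy() for c in self.children],
        )


class Tree:
    """Unrooted topology with optional branch lengths and supports.

    Stored as an arbitrarily rooted node structure; all comparisons
    (splits, quartets, consensus) are on the unrooted topology. Degree-2
    internal vertices are collapsed on construction, and a root with only
    two children is merged into a single basal multifurcation so that the
    rooted representation is canonical for the unrooted tree.
    """

    def __init__(self, root: Clade):
        self.root = _canonicalize(root)
        leaves = [n.name for n in self.root.iter_nodes() if n.is_leaf()]
        if any(name is None for name in leaves):
            raise NewickError("unnamed leaf")
        if len(set(leaves)) != len(leaves):
            dup = sorted({x for x in leaves if leaves.count(x) > 1})
            raise NewickError(f"duplicate leaves: {', '.join(dup)}")
        self.taxa: frozenset[str] = frozenset(leaves)

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    def splits(self) -> frozenset["Split"]:
        return tree_splits(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({write_newick(self)})"


def _canonicalize(root: Clade) -> Clade:
    """Suppress degree-2 vertices and two-child roots (branch lengths sum)."""

    def suppress(node: Clade) -> Clade:
        node.children = [suppress(c) for c in node.children]
        if len(node.children) == 1 and node.children:
            child = node.children[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            return child
        return node

    root = suppress(root)
    # Unroot: merge a bifurcating root by splicing one internal child up.
    while len(root.children) == 2:
        a, b = root.children
        internal = b if not b.is_leaf() else a if not a.is_leaf() else None
        if internal is None:
            break  # two-leaf tree ("cherry") stays as is
        other = a if internal is b else b
        if other.length is not None or internal.length is not None:
            other.length = (other.length or 0.0) + (internal.length or 0.0)
        root.children = [other] + internal.children
        root.support = None
    return root


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy; writing is ours so support
# labels render with a fixed format)
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> Tree:
    """Parse one Newick string into an unrooted :class:`Tree`.

    Internal node labels are interpreted as support values when they are
    numeric and in [0, 1]; otherwise they are kept as names.
    """
    text = text.strip()
    if not text:
        raise NewickError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickError(f"cannot parse Newick: {exc}") from exc

    def convert(dnode) -> Clade:
        node = Clade(length=dnode.edge.length)
        if dnode.is_leaf():
            if dnode.taxon is None:
                raise NewickError("unnamed leaf")
            node.name = dnode.taxon.label
        else:
            label = dnode.label
            if label is not None:
                try:
                    val = float(label)
                except ValueError:
                    node.name = label
                else:
                    if 0.0 <= val <= 1.0:
                        node.support = val
                    else:
                        node.name = label
            node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return Tree(convert(dtree.seed_node))


def _format_length(x: float) -> str:
    s = f"{x:.10f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_newick(tree: Tree, support_decimals: int = 4) -> str:
    """Render a tree as Newick; supports become internal node labels."""

    def render(node: Clade) -> str:
        if node.is_leaf():
            out = node.name or ""
        else:
            inner = ",".join(render(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = f"{node.support:.{support_decimals}f}"
            elif node.name:
                label = node.name
            out = f"({inner}){label}"
        if node.length is not None:
            out += f":{_format_length(node.length)}"
        return out

    return render(tree.root) + ";"


def read_treelist(path: str | Path) -> list[Tree]:
    """Read a plain-text treelist: one Newick per line."""
    trees = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            trees.append(parse_newick(line))
    if not trees:
        raise NewickError(f"{path}: no trees")
    return trees


def write_treelist(trees: list[Tree], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

class Split:
    """An unordered bipartition of a taxon universe.

    Canonical encoding: ``side1`` is the side containing the
    lexicographically smallest taxon of the universe. Only nontrivial
    splits (both sides >= 2 taxa) are constructed.
    """

    __slots__ = ("side1", "side2", "_hash")

    def __init__(self, side_a: frozenset[str], side_b: frozenset[str]):
        if side_a & side_b:
            raise ValueError("split sides overlap")
        if len(side_a) < 2 or len(side_b) < 2:
            raise ValueError("trivial split (a side has < 2 taxa)")
        if min(side_a) > min(side_b):
            side_a, side_b = side_b, side_a
        self.side1 = side_a
        self.side2 = side_b
        self._hash = hash((self.side1, self.side2))

    @property
    def universe(self) -> frozenset[str]:
        return self.side1 | self.side2

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Split)
            and self.side1 == other.side1
            and self.side2 == other.side2
        )

    def __hash__(self) -> int:
        return self._hash

    def key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Deterministic sort key (canonical encoding)."""
        return (tuple(sorted(self.side1)), tuple(sorted(self.side2)))

    def __repr__(self) -> str:
        return (
            ",".join(sorted(self.side1)) + "|" + ",".join(sorted(self.side2))
        )

    def restrict(self, taxa: frozenset[str]) -> "Split | None":
        """Restriction to a leaf subset, or None if it becomes trivial."""
        a = self.side1 & taxa
        b = self.side2 & taxa
        if len(a) < 2 or len(b) < 2:
            return None
        return Split(a, b)


def tree_splits(tree: Tree) -> frozenset[Split]:
    """Nontrivial bipartitions, one per internal edge of the unrooted tree."""
    universe = tree.taxa
    out: set[Split] = set()

    def clusters(node: Clade) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(clusters(c) for c in node.children))
        if node is not tree.root:
            rest = universe - below
            if len(below) >= 2 and len(rest) >= 2:
                out.add(Split(below, rest))
        return below

    clusters(tree.root)
    return frozenset(out)


def _support_map(tree: Tree) -> dict[Split, float | None]:
    """Split -> support label for each internal edge of *tree*."""
    universe = tree.taxa
    out: dict[Split, float | None] = {}

    def walk(node: Clade) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if node is not tree.root:
            rest = universe - below
            if len(below) >= 2 and len(rest) >= 2:
                out[Split(below, rest)] = node.support
        return below

    walk(tree.root)
    return out


def splits_compatible(s1: Split, s2: Split) -> bool:
    """Four-intersection test: compatible iff some side pair is disjoint."""
    return (
        not (s1.side1 & s2.side1)
        or not (s1.side1 & s2.side2)
        or not (s1.side2 & s2.side1)
        or not (s1.side2 & s2.side2)
    )


@dataclass(frozen=True)
class SplitFrequencies:
    """Per-split vote counts over a treelist.

    ``rows[s] = (supporting, informative, frequency)``: a tree is
    informative for a split when both restricted sides keep >= 2 taxa, and
    supporting when the restriction is one of its own splits.
    """

    universe: frozenset[str]
    n_trees: int
    rows: dict[Split, tuple[int, int, float]]

    def frequency(self, split: Split) -> float:
        return self.rows[split][2]


def _lift(split: Split, tree_taxa: frozenset[str], universe: frozenset[str]) -> Split:
    """Extend a partial tree's split to the universe.

    Taxa missing from the tree are grouped with the side holding the
    smallest universe taxon present in the tree — a deterministic
    convention; vote counting afterwards uses exact restriction, so the
    reported frequency of every candidate is exact.
    """
    missing = universe - tree_taxa
    if not missing:
        return split
    anchor = min(tree_taxa)
    if anchor in split.side1:
        return Split(split.side1 | missing, split.side2)
    return Split(split.side1, split.side2 | missing)


def split_frequencies(trees: list[Tree]) -> SplitFrequencies:
    """Count, for every candidate bipartition, the trees supporting it.

    The candidate set is harvested from the input trees themselves; with a
    uniform leaf set this is exactly the classical bipartition table. With
    variable leaf sets, partial splits are lifted to the union universe
    (see :func:`_lift`) and each tree votes only where informative.
    """
    if not trees:
        raise ValueError("empty treelist")
    universe = frozenset().union(*(t.taxa for t in trees))
    per_tree: list[tuple[frozenset[str], frozenset[Split]]] = []
    candidates: set[Split] = set()
    for t in trees:
        sp = tree_splits(t)
        per_tree.append((t.taxa, sp))
        for s in sp:
            candidates.add(_lift(s, t.taxa, universe))
    rows: dict[Split, tuple[int, int, float]] = {}
    for cand in candidates:
        supporting = informative = 0
        for taxa, splitset in per_tree:
            r = cand if len(taxa) == len(universe) else cand.restrict(taxa)
            if r is None:
                continue
            informative += 1
            if r in splitset:
                supporting += 1
        rows[cand] = (supporting, informative, supporting / informative)
    return SplitFrequencies(universe=universe, n_trees=len(trees), rows=rows)


def tree_from_splits(
    splits: dict[Split, float | None], universe: frozenset[str]
) -> Tree:
    """Assemble the unrooted tree displaying a compatible split set.

    Each split's value becomes the support label of its edge. Taxa not
    separated by any accepted split hang off the basal multifurcation.
    """
    anchor = min(universe) if universe else ""
    # Root at the anchor taxon: each split's anchor-free side is a cluster;
    # compatibility makes the cluster family laminar.
    clusters: list[tuple[frozenset[str], float | None]] = []
    for s, supp in splits.items():
        side = s.side2 if anchor in s.side1 else s.side1
        clusters.append((side, supp))
    clusters.sort(key=lambda cs: (-len(cs[0]), tuple(sorted(cs[0]))))

    root = Clade()
    node_cluster: dict[int, frozenset[str]] = {id(root): universe}
    nodes = [root]

    for cl, supp in clusters:
        # parent = minimal placed cluster containing cl (laminarity makes
        # this unique); clusters are placed largest-first so it exists
        best = root
        for nd in nodes:
            c = node_cluster[id(nd)]
            if cl <= c and len(c) < len(node_cluster[id(best)]):
                best = nd
        new = Clade(support=supp)
        node_cluster[id(new)] = cl
        best.children.append(new)
        nodes.append(new)

    # attach each leaf to the smallest cluster containing it
    for taxon in sorted(universe):
        best = root
        for nd in nodes:
            c = node_cluster[id(nd)]
            if taxon in c and len(c) < len(node_cluster[id(best)]):
                best = nd
        best.children.append(Clade(name=taxon))

    # deterministic child order: leaves then subclades, by smallest taxon
    def sort_children(node: Clade) -> frozenset[str]:
        keys = {}
        for c in node.children:
            keys[id(c)] = min(sort_children(c)) if c.children else c.name
        node.children.sort(key=lambda c: keys[id(c)])
        return frozenset(
            t for c in node.children
            for t in (node_cluster.get(id(c)) or frozenset([c.name]))
        )

    sort_children(root)
    return Tree(root)


def consensus_tree(trees: list[Tree], threshold: float) -> Tree:
    """Greedy threshold consensus over a treelist.

    Candidate splits are ranked by (frequency desc, canonical encoding
    asc); a split is accepted when its frequency >= *threshold* (inclusive)
    and it is compatible with everything already accepted. For thresholds
    above 0.5 this coincides with plain majority-threshold consensus; below
    0.5 it is the plurality (greedy) consensus.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    freqs = split_frequencies(trees)
    ranked = sorted(
        freqs.rows.items(), key=lambda kv: (-kv[1][2], kv[0].key())
    )
    accepted: dict[Split, float | None] = {}
    for split, (_supp, _inf, f) in ranked:
        if f < threshold:
            break
        if all(splits_compatible(split, other) for other in accepted):
            accepted[split] = f
    return tree_from_splits(accepted, freqs.universe)


def restrict_tree(tree: Tree, taxa: frozenset[str]) -> Tree:
    """Induced subtree on a leaf subset (degree-2 vertices suppressed)."""
    keep = tree.taxa & taxa
    if len(keep) < 2:
        raise ValueError(f"restriction keeps {len(keep)} leaves (< 2)")

    def prune(node: Clade) -> Clade | None:
        if node.is_leaf():
            return node.copy() if node.name in keep else None
        kept = [p for p in (prune(c) for c in node.children) if p is not None]
        if not kept:
            return None
        new = Clade(name=node.name, length=node.length, support=node.support)
        new.children = kept
        return new

    pruned = prune(tree.root)
    assert pruned is not None
    return Tree(pruned)
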