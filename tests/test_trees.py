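"""Newick I/O, bipartitions, split frequencies and greedy consensus.

Consensus supports are cross-checked against a brute-force counter that
enumerates every possible bipartition of the taxon universe and counts
supporting trees via dendropy's independent bipartition encoding.
"""

import itertools
import random

import dendropy
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_tuple_tree, tuple_tree_newick
from scoutknife.trees import (
    NewickError,
    Split,
    consensus_tree,
    parse_newick,
    read_treelist,
    restrict_tree,
    split_frequencies,
    splits_compatible,
    tree_from_splits,
    tree_splits,
    write_newick,
    write_treelist,
)


def S(left: str, right: str) -> Split:
    return Split(frozenset(left.split()), frozenset(right.split()))


def split_pairs(tree) -> set[frozenset[frozenset[str]]]:
    return {frozenset([s.side1, s.side2]) for s in tree_splits(tree)}


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


class TestNewick:
    def test_basic_parse(self):
        t = parse_newick("(A,B,(C,D));")
        assert t.taxa == frozenset("ABCD")
        assert split_pairs(t) == {frozenset([frozenset("CD"), frozenset("AB")])}

    def test_support_label_parsed(self):
        t = parse_newick("((A:1,B:2)0.75:3,(C,D));")
        supports = {
            frozenset([s.side1, s.side2]): sup
            for s, sup in _edge_supports(t).items()
        }
        assert supports[frozenset([frozenset("AB"), frozenset("CD")])] == 0.75

    def test_round_trip_preserves_everything(self):
        src = "((A:1,B:2)0.7500:3,C:0.5,(D:1,E:1)0.2500:2);"
        t1 = parse_newick(src)
        t2 = parse_newick(write_newick(t1))
        assert split_pairs(t1) == split_pairs(t2)
        assert _edge_supports(t1) == _edge_supports(t2)
        assert write_newick(t1) == write_newick(t2)

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(NewickError):
            parse_newick("((A,B,(C,D));")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(NewickError, match="duplicate"):
            parse_newick("((A,B),(A,C));")

    def test_rooted_input_is_unrooted(self):
        rooted = parse_newick("((A,B),(C,D));")
        assert len(rooted.root.children) == 3
        assert split_pairs(rooted) == split_pairs(parse_newick("(A,B,(C,D));"))

    def test_treelist_round_trip(self, tmp_path):
        trees = [parse_newick(s) for s in ["((A,B),(C,D));", "(A,C,(B,D));"]]
        path = tmp_path / "list.nwk"
        write_treelist(trees, path)
        back = read_treelist(path)
        assert [split_pairs(t) for t in back] == [split_pairs(t) for t in trees]


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(4, 10))
def test_newick_round_trip_random_trees(seed, n_taxa):
    rng = random.Random(seed)
    tup = random_tuple_tree(rng, [f"t{i}" for i in range(n_taxa)])
    t1 = parse_newick(tuple_tree_newick(tup))
    t2 = parse_newick(write_newick(t1))
    assert split_pairs(t1) == split_pairs(t2)
    assert write_newick(t1) == write_newick(t2)


def _edge_supports(tree):
    from scoutknife.trees import _support_map

    return _support_map(tree)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


class TestTreeSplits:
    def test_quartet_tree(self):
        assert split_pairs(parse_newick("((A,B),(C,D));")) == {
            frozenset([frozenset("AB"), frozenset("CD")])
        }

    def test_star_has_none(self):
        assert tree_splits(parse_newick("(A,B,C,D);")) == frozenset()

    def test_caterpillar(self):
        t = parse_newick("((((A,B),C),D),E);")
        assert split_pairs(t) == {
            frozenset([frozenset("AB"), frozenset("CDE")]),
            frozenset([frozenset("ABC"), frozenset("DE")]),
        }

    def test_compatibility_four_point(self):
        assert splits_compatible(S("A B", "C D E"), S("A B C", "D E"))
        assert not splits_compatible(S("A B", "C D"), S("A C", "B D"))

    def test_restriction(self):
        sp = S("A B", "C D E")
        assert sp.restrict(frozenset("ABCD")) == S("A B", "C D")
        assert sp.restrict(frozenset("ACD")) is None  # one side shrinks to 1


class TestRestrictTree:
    def test_induced_subtree(self):
        t = parse_newick("((((A,B),C),D),(E,F));")
        r = restrict_tree(t, frozenset("ABEF"))
        assert r.taxa == frozenset("ABEF")
        assert split_pairs(r) == {frozenset([frozenset("AB"), frozenset("EF")])}

    def test_polytomy_preserved(self):
        t = parse_newick("((A,B,C),(D,E));")
        r = restrict_tree(t, frozenset("ABCDE") - {"E"})
        assert r.taxa == frozenset("ABCD")


# ---------------------------------------------------------------------------
# frequencies & consensus
# ---------------------------------------------------------------------------

THREE_TREES = ["((A,B),(C,D));", "((A,B),(C,D));", "((A,C),(B,D));"]


class TestSplitFrequencies:
    def test_direct_count(self):
        trees = [parse_newick(s) for s in THREE_TREES]
        f = split_frequencies(trees)
        assert f.rows[S("A B", "C D")] == (2, 3, pytest.approx(2 / 3))

    def test_partial_tree_is_uninformative(self):
        trees = [parse_newick(s) for s in THREE_TREES + ["(A,B,C);"]]
        f = split_frequencies(trees)
        supporting, informative, freq = f.rows[S("A B", "C D")]
        assert (supporting, informative) == (2, 3)
        assert freq == pytest.approx(2 / 3)

    def test_identical_trees_all_one(self):
        trees = [parse_newick("((((A,B),C),D),E);")] * 4
        f = split_frequencies(trees)
        assert all(v[2] == 1.0 for v in f.rows.values())

    def test_empty_treelist_rejected(self):
        with pytest.raises(ValueError):
            split_frequencies([])


class TestConsensus:
    def test_majority_example(self):
        trees = [parse_newick(s) for s in THREE_TREES]
        cons = consensus_tree(trees, 0.5)
        assert split_pairs(cons) == {frozenset([frozenset("AB"), frozenset("CD")])}
        (support,) = [s for s in _edge_supports(cons).values()]
        assert support == pytest.approx(2 / 3, abs=1e-9)

    def test_seventy_percent_collapses_to_star(self):
        trees = [parse_newick(s) for s in THREE_TREES]
        assert split_pairs(consensus_tree(trees, 0.7)) == set()

    def test_greedy_rule_excludes_conflicting_runner_up(self):
        # frequencies: AB|CD 0.4 (8/20), AC|BD 0.35 (7/20), rest stars
        trees = (
            [parse_newick("((A,B),(C,D),E);")] * 8
            + [parse_newick("((A,C),(B,D),E);")] * 7
            + [parse_newick("(A,B,C,D,E);")] * 5
        )
        cons = consensus_tree(trees, 0.3)
        assert split_pairs(cons) == {
            frozenset([frozenset("AB"), frozenset("CDE")]),
            frozenset([frozenset("CD"), frozenset("ABE")]),
        }

    def test_exact_threshold_split_is_kept(self):
        trees = [parse_newick("((A,B),(C,D));")] * 7 + [
            parse_newick("(A,B,C,D);")
        ] * 3
        cons = consensus_tree(trees, 0.7)
        assert split_pairs(cons) == {frozenset([frozenset("AB"), frozenset("CD")])}

    def test_identical_trees_reproduced_with_full_support(self):
        t = parse_newick("((((A,B),C),D),(E,F));")
        for thr in (0.3, 0.5, 0.7, 1.0):
            cons = consensus_tree([t] * 5, thr)
            assert split_pairs(cons) == split_pairs(t)
            assert all(v == 1.0 for v in _edge_supports(cons).values())

    def test_threshold_monotonicity(self):
        rng = random.Random(17)
        taxa = [f"t{i}" for i in range(7)]
        trees = [
            parse_newick(tuple_tree_newick(random_tuple_tree(rng, taxa)))
            for _ in range(9)
        ]
        prev = None
        for thr in (0.9, 0.7, 0.5, 0.3):
            got = split_pairs(consensus_tree(trees, thr))
            if prev is not None:
                assert prev <= got
            prev = got

    def test_accepted_splits_pairwise_compatible(self):
        rng = random.Random(23)
        taxa = [f"t{i}" for i in range(8)]
        for trial in range(10):
            trees = [
                parse_newick(tuple_tree_newick(random_tuple_tree(rng, taxa)))
                for _ in range(7)
            ]
            cons = consensus_tree(trees, 0.25)
            sps = list(tree_splits(cons))
            for a, b in itertools.combinations(sps, 2):
                assert splits_compatible(a, b)


# ---------------------------------------------------------------------------
# brute-force oracle: frequency of every possible bipartition, counted via
# dendropy's independent encoding
# ---------------------------------------------------------------------------


def dendropy_split_sets(newicks, taxa):
    tns = dendropy.TaxonNamespace(list(taxa))
    out = []
    for nwk in newicks:
        dt = dendropy.Tree.get(
            data=nwk, schema="newick", taxon_namespace=tns,
            preserve_underscores=True,
        )
        dt.is_rooted = False
        dt.update_bipartitions()
        sets = set()
        for bp in dt.bipartition_encoding:
            side = frozenset(
                t.label for t in tns.bitmask_taxa_list(bp.leafset_bitmask)
            )
            if 2 <= len(side) <= len(taxa) - 2:
                sets.add(frozenset([side, frozenset(taxa) - side]))
        out.append(sets)
    return out


def all_bipartitions(taxa):
    taxa = sorted(taxa)
    rest = taxa[1:]
    for r in range(1, len(rest)):
        for combo in itertools.combinations(rest, r):
            side = frozenset(combo) | {taxa[0]}
            other = frozenset(taxa) - side
            if len(side) >= 2 and len(other) >= 2:
                yield frozenset([side, other])


def test_consensus_supports_match_brute_force_counts():
    """Supports on consensus edges equal exhaustive per-bipartition counts."""
    rng = random.Random(31)
    for trial in range(12):
        n_taxa = rng.randint(5, 8)
        taxa = [f"t{i}" for i in range(n_taxa)]
        newicks = [
            tuple_tree_newick(random_tuple_tree(rng, taxa)) for _ in range(rng.randint(4, 9))
        ]
        trees = [parse_newick(n) for n in newicks]
        oracle_sets = dendropy_split_sets(newicks, taxa)
        oracle_freq = {
            bp: sum(bp in s for s in oracle_sets) / len(oracle_sets)
            for bp in all_bipartitions(taxa)
        }
        # frequencies agree exactly for every split the package reports
        f = split_frequencies(trees)
        for sp, (_supp, _inf, freq) in f.rows.items():
            assert freq == pytest.approx(
                oracle_freq[frozenset([sp.side1, sp.side2])], abs=0
            )
        # consensus supports equal the oracle frequencies
        for thr in (0.5, 0.3):
            cons = consensus_tree(trees, thr)
            for sp, supp in _edge_supports(cons).items():
                assert supp == pytest.approx(
                    oracle_freq[frozenset([sp.side1, sp.side2])], abs=0
                )


def test_tree_from_splits_reconstructs_topology():
    t = parse_newick("((((A,B),C),D),(E,F));")
    rebuilt = tree_from_splits(
        {s: 1.0 for s in tree_splits(t)}, t.taxa
    )
    assert split_pairs(rebuilt) == split_pairs(t)
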