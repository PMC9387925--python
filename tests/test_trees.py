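"""Character matrix, Fitch parsimony, tree search and quartet supertree."""

import itertools

import pytest

from indelphy import (
    CharacterMatrix,
    QuartetTopology,
    SupportCall,
    build_character_matrix,
    enumerate_topologies,
    enumerate_unrooted_trees,
    export_matrix_nexus,
    export_matrix_phylip,
    export_quartets,
    induced_quartet,
    parse_matrix_nexus,
    parse_matrix_phylip,
    parse_quartets,
    parsimony_score,
    quartet_supertree,
    rf_distance,
    search_parsimony_tree,
)
from indelphy.pairs import BlockPair
from indelphy.topology import classify_support
from indelphy.trees import adj_from_tree, tree_from_adj


def _pair(distances):
    return BlockPair(b1=None, b2=None, distances=distances,
                     support=classify_support(distances))


TAXA8 = tuple(f"S{i}" for i in range(1, 9))


def test_strong_column_encoding():
    pair = _pair({"S2": 2, "S4": 3, "S5": 2, "S8": 3})
    m = build_character_matrix([pair], TAXA8)
    col = m.column(0)
    assert (col["S2"], col["S4"], col["S5"], col["S8"]) == ("0", "1", "0", "1")
    assert [col[t] for t in TAXA8 if t not in pair.distances] == ["-"] * 4


def test_weak_column_encoding():
    pair = _pair({"S1": 2, "S4": 2, "S5": 3, "S6": 4})
    m = build_character_matrix([pair], tuple(f"S{i}" for i in range(1, 7)))
    col = m.column(0)
    assert (col["S1"], col["S4"], col["S5"], col["S6"]) == ("0", "0", "1", "2")


def test_empty_and_invalid_matrix():
    m = build_character_matrix([], ("a", "b", "c", "d"))
    assert m.ncols == 0
    uninformative = _pair({"a": 1, "b": 2, "c": 3, "d": 4})
    with pytest.raises(ValueError):
        build_character_matrix([uninformative], ("a", "b", "c", "d"))


def quartet_tree(top: QuartetTopology):
    a, b = top.cherry1
    c, d = top.cherry2
    return {
        0: [a, b, 1], 1: [c, d, 0],
        a: [0], b: [0], c: [1], d: [1],
    }


def test_parsimony_single_strong_column():
    pair = _pair({"a": 2, "b": 2, "c": 5, "d": 5})
    m = build_character_matrix([pair], ("a", "b", "c", "d"))
    supported = pair.support.topology
    for top in enumerate_topologies(("a", "b", "c", "d")):
        expected = 1 if top == supported else 2
        assert parsimony_score(quartet_tree(top), m) == expected


def test_parsimony_all_missing_column():
    m = CharacterMatrix(taxa=("a", "b", "c", "d", "e", "f"),
                        rows=("0", "1", "-", "-", "-", "-"))
    blank = CharacterMatrix(taxa=m.taxa, rows=tuple("-" for _ in m.taxa))
    tree = next(enumerate_unrooted_trees(m.taxa))
    assert parsimony_score(tree, blank) == 0


def brute_force_parsimony(adj, matrix):
    """Enumerate all internal-node state assignments; missing leaves are
    free (cost 0 on their edge)."""
    internal = [n for n in adj if isinstance(n, int)]
    row_of = dict(zip(matrix.taxa, matrix.rows))
    total = 0
    for j in range(matrix.ncols):
        best = 10**9
        for assign in itertools.product("012", repeat=len(internal)):
            state = dict(zip(internal, assign))
            cost = 0
            seen = set()
            for u in adj:
                for v in adj[u]:
                    if (v, u) in seen:
                        continue
                    seen.add((u, v))
                    su = state[u] if isinstance(u, int) else row_of.get(u, "-")[j]
                    sv = state[v] if isinstance(v, int) else row_of.get(v, "-")[j]
                    if su != "-" and sv != "-" and su != sv:
                        cost += 1
            best = min(best, cost)
        total += best
    return total


def test_parsimony_matches_brute_force(rng):
    """Fitch with missing data equals exhaustive internal labelling on
    random 6-taxon matrices and random topologies."""
    taxa = tuple("abcdef")
    all_trees = list(enumerate_unrooted_trees(taxa))
    for _ in range(12):
        rows = tuple(
            "".join(rng.choice(list("012-"), size=4)) for _ in taxa
        )
        m = CharacterMatrix(taxa=taxa, rows=rows)
        adj = all_trees[rng.integers(len(all_trees))]
        assert parsimony_score(adj, m) == brute_force_parsimony(adj, m)


def test_parsimony_taxon_mismatch():
    m = CharacterMatrix(taxa=("a", "b", "c", "x"), rows=("0", "0", "1", "1"))
    tree = quartet_tree(QuartetTopology.of("a", "b", "c", "d"))
    with pytest.raises(ValueError):
        parsimony_score(tree, m)


def test_enumerate_tree_counts():
    assert sum(1 for _ in enumerate_unrooted_trees("abcd")) == 3
    assert sum(1 for _ in enumerate_unrooted_trees("abcde")) == 15
    assert sum(1 for _ in enumerate_unrooted_trees("abcdef")) == 105


def test_search_single_strong_column_four_taxa():
    pair = _pair({"a": 0, "b": 7, "c": 0, "d": 7})
    m = build_character_matrix([pair], ("a", "b", "c", "d"))
    tree = search_parsimony_tree(m, mode="exhaustive")
    assert induced_quartet(tree, ("a", "b", "c", "d")) == pair.support.topology
    with pytest.raises(ValueError):
        search_parsimony_tree(CharacterMatrix(taxa=("a", "b", "c"),
                                              rows=("0", "1", "1")))


def test_search_exhaustive_on_six_taxon_matrix(fixtures):
    """The exhaustive search attains the enumeration optimum over all 105
    six-leaf topologies on the four-strong-column worked matrix."""
    m = fixtures["fig5"]["matrix"]
    scores = [parsimony_score(adj, m) for adj in enumerate_unrooted_trees(m.taxa)]
    tree = search_parsimony_tree(m, mode="exhaustive")
    assert parsimony_score(adj_from_tree(tree), m) == min(scores)


def test_heuristic_matches_exhaustive(rng):
    """Stepwise addition + TBR reaches the global optimum on random
    strong/weak matrices with up to 7 taxa."""
    for trial in range(10):
        n = int(rng.integers(5, 8))
        taxa = tuple(f"t{i}" for i in range(n))
        pairs = []
        for _ in range(6):
            four = rng.choice(n, size=4, replace=False)
            ids = [taxa[i] for i in sorted(four)]
            if rng.random() < 0.7:
                d = dict(zip(ids, [0, 0, 1, 1] if rng.random() < 0.5 else [0, 1, 0, 1]))
            else:
                d = dict(zip(ids, [0, 0, 1, 2]))
            pairs.append(_pair(d))
        m = build_character_matrix(pairs, taxa)
        exact = parsimony_score(
            adj_from_tree(search_parsimony_tree(m, mode="exhaustive")), m
        )
        heur = parsimony_score(
            adj_from_tree(search_parsimony_tree(m, mode="heuristic", rng_seed=trial)), m
        )
        assert heur == exact


def test_weak_columns_cost_two_everywhere(rng):
    """A weak column is parsimony-uninformative: cost 2 on every tree, so
    dropping weak columns never changes the optimum on strong data."""
    taxa = tuple("abcdef")
    weak = build_character_matrix(
        [_pair({"a": 1, "b": 1, "c": 2, "d": 3})], taxa
    )
    trees_ = list(enumerate_unrooted_trees(taxa))
    for adj in [trees_[i] for i in rng.integers(0, len(trees_), size=15)]:
        assert parsimony_score(adj, weak) == 2


def test_strong_column_score_is_quartet_cost(rng):
    """Per-column cost on strong-only matrices equals 1 if the tree
    displays the column's quartet, else 2."""
    taxa = tuple("abcdef")
    all_trees = list(enumerate_unrooted_trees(taxa))
    for _ in range(10):
        four = sorted(rng.choice(6, size=4, replace=False))
        ids = [taxa[i] for i in four]
        pair = _pair(dict(zip(ids, [0, 0, 3, 3])))
        m = build_character_matrix([pair], taxa)
        adj = all_trees[rng.integers(len(all_trees))]
        displayed = induced_quartet(tree_from_adj(adj), ids) == pair.support.topology
        assert parsimony_score(adj, m) == (1 if displayed else 2)


# ---------------------------------------------------------------------------
# quartet supertree


def test_supertree_recovers_tree_from_all_quartets():
    from indelphy import read_newick

    ref = read_newick("((A,B),((C,D),(E,F)));")
    calls = [
        (induced_quartet(ref, q), 1)
        for q in itertools.combinations("ABCDEF", 4)
    ]
    tree = quartet_supertree(calls, rng_seed=0)
    assert rf_distance(tree, ref) == 0


def test_supertree_single_and_majority_quartet():
    single = quartet_supertree([(QuartetTopology.of("a", "b", "c", "d"), 1)])
    assert induced_quartet(single, "abcd") == QuartetTopology.of("a", "b", "c", "d")
    majority = quartet_supertree(
        [
            (QuartetTopology.of("1", "2", "3", "4"), 10),
            (QuartetTopology.of("1", "3", "2", "4"), 1),
        ]
    )
    assert induced_quartet(majority, "1234") == QuartetTopology.of("1", "2", "3", "4")
    with pytest.raises(ValueError):
        quartet_supertree([])


def test_supertree_label_permutation_equivariance(rng):
    from indelphy import read_newick

    ref = read_newick("(((A,B),(C,D)),((E,F),(G,H)));")
    taxa = list("ABCDEFGH")
    calls = [
        (induced_quartet(ref, q), 1) for q in itertools.combinations(taxa, 4)
    ]
    perm = taxa.copy()
    rng.shuffle(perm)
    mapping = dict(zip(taxa, perm))
    permuted_calls = [
        (
            QuartetTopology.of(
                mapping[t.cherry1[0]], mapping[t.cherry1[1]],
                mapping[t.cherry2[0]], mapping[t.cherry2[1]],
            ),
            w,
        )
        for t, w in calls
    ]
    tree = quartet_supertree(calls, rng_seed=1)
    permuted_tree = quartet_supertree(permuted_calls, rng_seed=1)
    # relabel the permuted result back and compare
    back = {v: k for k, v in mapping.items()}
    for leaf in permuted_tree.leaf_node_iter():
        leaf.taxon.label = back[leaf.taxon.label]
    assert rf_distance(tree, permuted_tree) == 0


# ---------------------------------------------------------------------------
# exporters


def test_quartet_list_roundtrip():
    calls = [
        (QuartetTopology.of("a", "b", "c", "d"), 3),
        (QuartetTopology.of("a", "c", "b", "e"), 1),
    ]
    text = export_quartets(calls)
    assert text.count("a,b|c,d") == 3
    assert parse_quartets(text) == sorted(calls)


def test_phylip_and_nexus_roundtrip(fixtures):
    m = fixtures["fig5"]["matrix"]
    phy = export_matrix_phylip(m)
    assert phy.splitlines()[0].split() == ["6", "4"]
    assert parse_matrix_phylip(phy) == m
    nex = export_matrix_nexus(m)
    assert nex.startswith("#NEXUS")
    assert parse_matrix_nexus(nex) == m
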