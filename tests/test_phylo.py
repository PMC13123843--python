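"""JC69 distances, UPGMA clustering (vs scipy oracle), bootstrap,
unique-mutation branch lengths."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from clonemosaic import phylo


def binmat(rows, samples=None):
    arr = np.asarray(rows, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=pd.Index(samples, name="sample"))


def test_jc69_closed_form_and_identity():
    m = binmat([[0] * 100, [0] * 100])
    assert phylo.jc69_distance(m).iloc[0, 1] == 0.0
    # p = 3/100 discordant columns
    row2 = [1] * 3 + [0] * 97
    d = phylo.jc69_distance(binmat([[0] * 100, row2])).iloc[0, 1]
    assert d == pytest.approx(-0.75 * np.log(1 - 0.04), abs=1e-12)
    assert f"{d:.6f}" == "0.030616"


def test_jc69_saturation_boundary():
    just_below = binmat([[0] * 4000, [1] * 2999 + [0] * 1001])  # p = 0.749750
    d = phylo.jc69_distance(just_below).iloc[0, 1]
    assert np.isfinite(d) and d > 2.0
    at_limit = binmat([[0] * 4, [1] * 3 + [0]])
    with pytest.raises(phylo.SaturationError):
        phylo.jc69_distance(at_limit)


def test_jc69_monotone_in_p():
    last = -1.0
    for k in range(0, 70):
        m = binmat([[0] * 100, [1] * k + [0] * (100 - k)])
        d = phylo.jc69_distance(m).iloc[0, 1]
        assert d > last
        last = d


def dist_df(labels, mat):
    return pd.DataFrame(np.asarray(mat, dtype=float), index=labels, columns=labels)


def test_upgma_hand_example_and_cherry():
    d = dist_df(["A", "B", "C"], [[0, 2, 8], [2, 0, 8], [8, 8, 0]])
    tree = phylo.upgma(d)
    assert tree.clades() == [frozenset("ABC"), frozenset("AB")] or frozenset("AB") in tree.clades()
    assert tree.newick(lengths=False, supports=False) == "((A,B),C);"

    cherry = phylo.upgma(dist_df(["X", "Y"], [[0, 3], [3, 0]]))
    assert cherry.newick(lengths=False, supports=False) == "(X,Y);"
    assert cherry.height == pytest.approx(1.5)

    with pytest.raises(ValueError):
        phylo.upgma(dist_df(["A", "B"], [[0, np.nan], [np.nan, 0]]))


def test_upgma_recovers_ultrametric_tree_and_matches_scipy():
    rng = np.random.default_rng(0)
    for trial in range(20):
        n = int(rng.integers(4, 9))
        # random ultrametric matrix from a random merge order
        Z = hierarchy.linkage(rng.random((n, 3)), method="average")
        D = squareform(hierarchy.cophenet(Z))
        labels = [f"t{i}" for i in range(n)]
        mine = phylo.upgma(dist_df(labels, D))
        # scipy average linkage on the same distances is the oracle
        Zs = hierarchy.linkage(squareform(D), method="average")
        oracle = {
            frozenset(labels[i] for i in leaves)
            for leaves in _scipy_clades(Zs, n)
        }
        assert set(mine.clades()) == oracle


def _scipy_clades(Z, n):
    members = {i: [i] for i in range(n)}
    out = []
    for k, (a, b, _h, _c) in enumerate(Z):
        merged = members[int(a)] + members[int(b)]
        members[n + k] = merged
        out.append(merged)
    return out


def test_upgma_taxon_order_invariance():
    rng = np.random.default_rng(1)
    n = 7
    Z = hierarchy.linkage(rng.random((n, 3)), method="average")
    D = squareform(hierarchy.cophenet(Z))
    labels = [f"t{i}" for i in range(n)]
    base = set(phylo.upgma(dist_df(labels, D)).clades())
    for _ in range(5):
        perm = rng.permutation(n)
        d2 = dist_df([labels[i] for i in perm], D[np.ix_(perm, perm)])
        assert set(phylo.upgma(d2).clades()) == base


def separated_clades_matrix():
    """Two clean 4-leaf clades with nested cherries, no homoplasy, and
    enough private background that no pair saturates."""
    samples = ["a1", "a2", "a3", "a4", "b1", "b2", "b3", "b4"]
    cols = []

    def col(carriers, n):
        for _ in range(n):
            cols.append([1 if s in carriers else 0 for s in samples])

    col({"a1", "a2", "a3", "a4"}, 12)
    col({"b1", "b2", "b3", "b4"}, 12)
    for cherry in ({"a1", "a2"}, {"a3", "a4"}, {"b1", "b2"}, {"b3", "b4"}):
        col(cherry, 8)
    for s in samples:
        col({s}, 6)
    return binmat(np.array(cols).T, samples=samples)


def test_bootstrap_trivial_cases():
    # two perfectly separated clades, no homoplasy -> unanimous support
    m = separated_clades_matrix()
    tree = phylo.bootstrap_support(m, B=50, seed=0)
    clades = {n.leaves() for n in tree.walk() if not n.is_leaf()}
    assert frozenset({"a1", "a2", "a3", "a4"}) in clades
    for node in tree.walk():
        if not node.is_leaf():
            assert node.support == 1.0

    tree1 = phylo.bootstrap_support(m, B=1, seed=1)
    for node in tree1.walk():
        if not node.is_leaf():
            assert node.support in (0.0, 1.0)

    with pytest.raises(ValueError):
        phylo.bootstrap_support(m, B=0)


def test_branch_lengths_partition_columns():
    # columns: private to a1; clade {a1,a2}; private to b1; clade {a1,a2,b1,b2}
    m = binmat(
        np.array(
            [
                [1, 1, 1, 0, 0, 1],
                [0, 1, 1, 0, 0, 1],
                [0, 0, 0, 1, 0, 1],
                [0, 0, 0, 0, 1, 1],
            ]
        ),
        samples=["a1", "a2", "b1", "b2"],
    )
    tree = phylo.build_tree(m)
    tree, homoplasy = phylo.branch_lengths_from_unique(m, tree)
    lengths = {n.leaves(): n.length for n in tree.walk()}
    assert lengths[frozenset({"a1"})] == 1
    assert lengths[frozenset({"a1", "a2"})] == 2
    assert lengths[frozenset({"b1"})] == 1
    assert homoplasy == 0
    assert sum(n.length for n in tree.walk()) + homoplasy == m.shape[1]


def test_branch_lengths_report_homoplasy():
    # fixed topology ((a,b),(c,d)); a column carried by {a,c} matches no clade
    tree = phylo.Clade(
        children=[
            phylo.Clade(children=[phylo.Clade(name="a"), phylo.Clade(name="b")]),
            phylo.Clade(children=[phylo.Clade(name="c"), phylo.Clade(name="d")]),
        ]
    )
    m = binmat(
        np.array([[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 1]]).T,
        samples=list("abcd"),
    )
    tree, homoplasy = phylo.branch_lengths_from_unique(m, tree)
    lengths = {n.leaves(): n.length for n in tree.walk()}
    assert lengths[frozenset({"a", "b"})] == 1
    assert lengths[frozenset({"d"})] == 1
    assert homoplasy == 1
    assert sum(n.length for n in tree.walk()) + homoplasy == m.shape[1]
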