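"""Nei DA distance, neighbour joining, bootstrap support, PCA, Newick I/O."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from mhcfam import (
    PopulationFrequencySet,
    bootstrap_support,
    distance_matrix,
    nei_da,
    nj_tree,
    pca_scores,
    write_newick,
)
from mhcfam.compare import _bipartitions, read_newick


def _pop(label, freqs_by_locus, two_n=200):
    return PopulationFrequencySet(
        label,
        {l: dict(t) for l, t in freqs_by_locus.items()},
        {l: two_n for l in freqs_by_locus},
    )


def _random_pops(n, rng, loci=("A", "B", "DRB1"), k=8):
    pops = []
    for i in range(n):
        freqs = {
            l: {f"{l}*{j:02d}": float(p) for j, p in
                enumerate(rng.dirichlet(np.ones(k)), 1)}
            for l in loci
        }
        pops.append(_pop(f"P{i}", freqs))
    return pops


# ---------------------------------------------------------------------------
# Nei DA


def test_da_identity_zero():
    x = _pop("X", {"A": {"a": 0.25, "b": 0.75}})
    assert nei_da(x, x) == 0.0


def test_da_disjoint_alleles_is_one():
    x = _pop("X", {"A": {"a": 1.0}, "B": {"c": 1.0}})
    y = _pop("Y", {"A": {"b": 1.0}, "B": {"d": 1.0}})
    assert nei_da(x, y) == 1.0


def test_da_closed_form():
    x = _pop("X", {"A": {"a": 1.0}})
    y = _pop("Y", {"A": {"a": 0.25, "b": 0.75}})
    assert math.isclose(nei_da(x, y), 0.5)


def test_da_no_shared_loci():
    with pytest.raises(ValueError):
        nei_da(_pop("X", {"A": {"a": 1.0}}), _pop("Y", {"B": {"a": 1.0}}))


def test_da_axioms_random():
    """Symmetry, zero diagonal, bounds on random frequency sets."""
    pops = _random_pops(6, np.random.default_rng(1))
    for i, x in enumerate(pops):
        for y in pops[i:]:
            d = nei_da(x, y)
            assert 0.0 <= d <= 1.0
            assert math.isclose(d, nei_da(y, x))
        assert nei_da(x, x) < 1e-12


def test_frequency_sum_validation():
    with pytest.raises(ValueError):
        PopulationFrequencySet("bad", {"A": {"a": 0.5, "b": 0.3}})


# ---------------------------------------------------------------------------
# neighbour joining


def _additive_matrix_from_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths -> additive distance
    matrix plus its true set of non-trivial bipartitions."""
    import itertools

    nodes = [frozenset([i]) for i in range(n_taxa)]
    children: dict = {}
    lengths = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = a | b
        children[parent] = (a, b)
        lengths[a] = float(rng.uniform(0.05, 1.0))
        lengths[b] = float(rng.uniform(0.05, 1.0))
        nodes = [x for x_i, x in enumerate(nodes) if x_i not in (i, j)] + [parent]
    root = nodes[0]

    def leaf_depths(node, acc):
        if len(node) == 1:
            return {next(iter(node)): acc}
        a, b = children[node]
        out = leaf_depths(a, acc + lengths[a])
        out.update(leaf_depths(b, acc + lengths[b]))
        return out

    # path distance = depth_a + depth_b - 2 * depth of LCA
    depth_of = {root: 0.0}
    stack = [root]
    while stack:
        node = stack.pop()
        if node in children:
            for ch in children[node]:
                depth_of[ch] = depth_of[node] + lengths[ch]
                stack.append(ch)
    leafset = {}

    def collect(node):
        if len(node) == 1:
            leafset[node] = node
            return node
        a, b = children[node]
        leafset[node] = collect(a) | collect(b)
        return leafset[node]

    collect(root)
    dist = np.zeros((n_taxa, n_taxa))
    for x, y in itertools.combinations(range(n_taxa), 2):
        # find LCA: smallest stored clade containing both
        lca = min(
            (node for node in leafset if {x, y} <= set(node)),
            key=len,
        )
        d = (depth_of[frozenset([x])] + depth_of[frozenset([y])]
             - 2 * depth_of[lca])
        dist[x, y] = dist[y, x] = d
    all_leaves = frozenset(range(n_taxa))
    parts = set()
    for clade in children:
        if 1 < len(clade) < n_taxa - 1:
            other = all_leaves - clade
            parts.add(min((frozenset(str(i) for i in clade),
                           frozenset(str(i) for i in other)),
                          key=lambda s: (len(s), sorted(s))))
    return dist, parts


def test_nj_three_taxa():
    dm = DistanceMatrix(np.array([[0.0, 2, 3], [2, 0, 3], [3, 3, 0]]),
                        ids=["A", "B", "C"])
    tree = nj_tree(dm)
    assert sorted(t.name for t in tree.tips()) == ["A", "B", "C"]


def test_nj_recovers_additive_topologies():
    """Saitou-Nei NJ is exact on additive matrices (random trees)."""
    rng = np.random.default_rng(2024)
    for _ in range(30):
        n = int(rng.integers(4, 8))
        dist, true_parts = _additive_matrix_from_tree(rng, n)
        dm = DistanceMatrix(dist, ids=[str(i) for i in range(n)])
        tree = nj_tree(dm)
        assert _bipartitions(tree) == true_parts


def test_nj_identical_rows_are_siblings():
    d = np.array(
        [
            [0.0, 0.0, 0.6, 0.7],
            [0.0, 0.0, 0.6, 0.7],
            [0.6, 0.6, 0.0, 0.3],
            [0.7, 0.7, 0.3, 0.0],
        ]
    )
    tree = nj_tree(DistanceMatrix(d, ids=list("WXYZ")))
    assert frozenset("WX") in _bipartitions(tree)


def test_nj_rejects_asymmetry():
    with pytest.raises(Exception):
        nj_tree(DistanceMatrix(np.array([[0, 1.0, 2], [1.5, 0, 2], [2, 2, 0]]),
                               ids=list("ABC")))


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_single_rep_support_binary():
    pops = _random_pops(5, np.random.default_rng(3))
    tree = bootstrap_support(pops, reps=1, mode="loci", seed=0)
    supports = {int(n.name) for n in tree.non_tips() if n.name}
    assert supports <= {0, 100}


def test_bootstrap_separated_clusters_full_support():
    """Two far-separated clusters get ~100% support for the separating edge
    under gene-copy resampling."""
    rng = np.random.default_rng(8)
    loci = ("A", "B", "DRB1")
    pops = []
    for i in range(4):
        cluster = i // 2
        freqs = {}
        for l in loci:
            base = {f"{l}*{cluster}{j}": 0.2 for j in range(5)}
            jitter = rng.dirichlet(np.ones(5)) * 0.02
            freqs[l] = {
                a: max(p + jitter[j] - 0.01, 0.001)
                for j, (a, p) in enumerate(base.items())
            }
            total = sum(freqs[l].values())
            freqs[l] = {a: p / total for a, p in freqs[l].items()}
        pops.append(_pop(f"P{i}", freqs, two_n=400))
    tree = bootstrap_support(pops, reps=100, mode="genes", seed=5)
    sep = frozenset(["P0", "P1"])
    support = {
        frozenset(t.name for t in n.tips()): int(n.name)
        for n in tree.non_tips()
        if n.name
    }
    key = [k for k in support if k in (sep, frozenset(["P2", "P3"]))]
    assert key and all(support[k] >= 95 for k in key)


def test_bootstrap_seed_reproducible(tmp_path):
    pops = _random_pops(5, np.random.default_rng(6))
    t1 = bootstrap_support(pops, reps=25, seed=9)
    t2 = bootstrap_support(pops, reps=25, seed=9)
    p1, p2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
    write_newick(t1, p1)
    write_newick(t2, p2)
    assert p1.read_text() == p2.read_text()


def test_bootstrap_genes_requires_sample_sizes():
    pops = _random_pops(3, np.random.default_rng(0))
    for p in pops:
        p.two_n = {}
    with pytest.raises(ValueError):
        bootstrap_support(pops, reps=2, mode="genes")


# ---------------------------------------------------------------------------
# PCA


def test_pca_identical_populations_identical_scores():
    pops = _random_pops(4, np.random.default_rng(11))
    twin = PopulationFrequencySet("P0twin", {l: dict(t) for l, t in pops[0].freqs.items()})
    scores, explained, labels = pca_scores(pops + [twin])
    i, j = labels.index("P0"), labels.index("P0twin")
    assert np.allclose(scores[i], scores[j])
    assert math.isclose(float(explained.sum()), 1.0, rel_tol=1e-9)


def test_pca_duplicate_population_preserves_original_distances():
    pops = _random_pops(5, np.random.default_rng(12))
    s1, _, l1 = pca_scores(pops)
    dup = pops + [PopulationFrequencySet("dup", {l: dict(t) for l, t in pops[2].freqs.items()})]
    s2, _, l2 = pca_scores(dup)

    def dists(s, labels):
        idx = [labels.index(p.label) for p in pops]
        pts = s[idx]
        return {
            (a, b): float(np.linalg.norm(pts[a] - pts[b]))
            for a in range(len(idx))
            for b in range(a + 1, len(idx))
        }

    d1, d2 = dists(s1, l1), dists(s2, l2)
    # duplicating a population moves the centroid but preserves the geometry
    for k in d1:
        assert math.isclose(d1[k], d2[k], rel_tol=1e-9, abs_tol=1e-12)


def test_pca_requires_two_populations():
    with pytest.raises(ValueError):
        pca_scores(_random_pops(1, np.random.default_rng(0)))


# ---------------------------------------------------------------------------
# Newick


def test_newick_roundtrip_topology(tmp_path):
    pops = _random_pops(6, np.random.default_rng(13))
    tree = bootstrap_support(pops, reps=10, seed=3)
    path = tmp_path / "tree.nwk"
    write_newick(tree, path)
    text = path.read_text()
    assert text.rstrip().endswith(";")
    back = read_newick(path)
    assert _bipartitions(back) == _bipartitions(tree)
    # support labels survive the round trip
    assert {n.name for n in back.non_tips() if n.name} == {
        n.name for n in tree.non_tips() if n.name
    }
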