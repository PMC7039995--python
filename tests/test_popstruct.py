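"""DA distance, neighbor joining, bootstrap support and PCA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hlapop import (
    PopulationFreqSet,
    bootstrap_support,
    da_distance,
    distance_matrix,
    frequency_matrix,
    nj_tree,
    pca,
)


def _pop(name, a_freqs, b_freqs=None):
    freqs = {"A": dict(a_freqs)}
    if b_freqs is not None:
        freqs["B"] = dict(b_freqs)
    return PopulationFreqSet(name, freqs)


def test_da_identity_and_disjoint_bounds():
    x = _pop("x", {"a1": 0.5, "a2": 0.5}, {"b1": 1.0})
    y = _pop("y", {"a1": 0.5, "a2": 0.5}, {"b1": 1.0})
    assert da_distance(x, y, ("A", "B")) == pytest.approx(0.0, abs=1e-12)
    z = _pop("z", {"a3": 0.6, "a4": 0.4}, {"b2": 1.0})
    assert da_distance(x, z, ("A", "B")) == pytest.approx(1.0)


def test_da_closed_form_single_locus():
    x = _pop("x", {"a1": 0.5, "a2": 0.5})
    y = _pop("y", {"a1": 1.0})
    assert da_distance(x, y, ("A",)) == pytest.approx(1 - math.sqrt(0.5))


def test_da_symmetry_and_missing_locus_error():
    x = _pop("x", {"a1": 0.3, "a2": 0.7})
    y = _pop("y", {"a1": 0.8, "a2": 0.2})
    assert da_distance(x, y, ("A",)) == pytest.approx(da_distance(y, x, ("A",)))
    with pytest.raises(ValueError, match="B"):
        da_distance(x, y, ("A", "B"))


# --- neighbor joining -------------------------------------------------------


def _tree_distance_matrix(edges, leaves):
    """Path-length matrix of a tree given as {(u,v): length} (test oracle)."""
    import networkx as nx

    g = nx.Graph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, weight=w)
    d = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    m = pd.DataFrame(
        [[d[i][j] for j in leaves] for i in leaves], index=leaves, columns=leaves
    )
    return m


def test_nj_three_taxa_closed_form():
    d = pd.DataFrame(
        [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
        index=list("abc"),
        columns=list("abc"),
    )
    tree = nj_tree(d)
    bl = {child.name: length for child, length in tree.children}
    assert bl["a"] == pytest.approx((5 + 9 - 10) / 2)
    assert bl["b"] == pytest.approx((5 + 10 - 9) / 2)
    assert bl["c"] == pytest.approx((9 + 10 - 5) / 2)


def test_nj_recovers_four_taxon_additive_tree():
    # ((a:2,b:3):1,(c:4,d:5)) as an unrooted additive tree
    edges = {("a", "u"): 2, ("b", "u"): 3, ("u", "v"): 1, ("c", "v"): 4, ("d", "v"): 5}
    d = _tree_distance_matrix(edges, list("abcd"))
    tree = nj_tree(d)
    assert tree.bipartitions() == {frozenset({"a", "b"})}
    # total tree length preserved
    def total(node):
        return sum(bl + total(ch) for ch, bl in node.children)

    assert total(tree) == pytest.approx(sum(edges.values()))


def _random_additive_tree(rng, leaves):
    """Random unrooted binary tree with positive branch lengths (oracle)."""
    nodes = list(leaves[:3])
    edges = {}
    center = "i0"
    for leaf in leaves[:3]:
        edges[(leaf, center)] = rng.uniform(0.5, 2.0)
    internal = 1
    for leaf in leaves[3:]:
        u, v = list(edges)[rng.integers(0, len(edges))]
        w = edges.pop((u, v))
        mid = f"i{internal}"
        internal += 1
        split = rng.uniform(0.2, 0.8) * w
        edges[(u, mid)] = split
        edges[(mid, v)] = w - split
        edges[(leaf, mid)] = rng.uniform(0.5, 2.0)
    return edges


def _bipartitions_of_edges(edges, leaves):
    import networkx as nx

    g = nx.Graph(list(edges))
    out = set()
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side = frozenset(l for l in leaves if l in comp)
        g.add_edge(u, v)
        if 2 <= len(side) <= len(leaves) - 2:
            other = frozenset(leaves) - side
            if len(side) > len(other) or (len(side) == len(other) and sorted(side) > sorted(other)):
                side = other
            out.add(side)
    return out


@pytest.mark.parametrize("n_leaves,seed", [(5, 0), (6, 1), (7, 2), (8, 3)])
def test_nj_recovers_random_additive_trees(n_leaves, seed):
    rng = np.random.default_rng(seed)
    leaves = [f"t{i}" for i in range(n_leaves)]
    edges = _random_additive_tree(rng, leaves)
    d = _tree_distance_matrix(edges, leaves)
    tree = nj_tree(d)
    assert tree.bipartitions() == _bipartitions_of_edges(edges, leaves)


def test_nj_five_taxa_against_exhaustive_topology_oracle():
    """The generating topology is the unique zero-residual fit among all 15."""
    rng = np.random.default_rng(9)
    leaves = [f"t{i}" for i in range(5)]
    edges = _random_additive_tree(rng, leaves)
    d = _tree_distance_matrix(edges, leaves)

    # enumerate all 15 unrooted binary topologies on 5 leaves by leaf addition
    def enumerate_topologies():
        base = {("t0", "c"): 1, ("t1", "c"): 1, ("t2", "c"): 1}
        tops = [base]
        for leaf, tag in (("t3", "x"), ("t4", "y")):
            new = []
            for t in tops:
                for edge in list(t):
                    e = dict(t)
                    e.pop(edge)
                    u, v = edge
                    e[(u, tag + u + v)] = 1
                    e[(tag + u + v, v)] = 1
                    e[(leaf, tag + u + v)] = 1
                    new.append(e)
            tops = new
        return tops

    def residual(top):
        # least-squares branch lengths for the topology; oracle fit
        import networkx as nx

        g = nx.Graph(list(top))
        edge_list = list(g.edges)
        rows, y = [], []
        for i, j in itertools.combinations(leaves, 2):
            path = nx.shortest_path(g, i, j)
            onpath = set(zip(path, path[1:])) | set(zip(path[1:], path))
            rows.append([1.0 if (u, v) in onpath else 0.0 for u, v in edge_list])
            y.append(d.loc[i, j])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        fitted = np.array(rows) @ sol
        return float(np.sum((fitted - np.array(y)) ** 2)), top

    fits = sorted((residual(t) for t in enumerate_topologies()), key=lambda rt: rt[0])
    best_res, best_top = fits[0]
    assert best_res == pytest.approx(0.0, abs=1e-12)
    assert fits[1][0] > 1e-6  # unique
    assert nj_tree(d).bipartitions() == _bipartitions_of_edges(best_top, leaves)


def test_nj_invariant_to_input_order():
    rng = np.random.default_rng(12)
    leaves = [f"t{i}" for i in range(6)]
    edges = _random_additive_tree(rng, leaves)
    d = _tree_distance_matrix(edges, leaves)
    perm = list(reversed(leaves))
    d2 = d.loc[perm, perm]
    assert nj_tree(d).bipartitions() == nj_tree(d2).bipartitions()


def test_nj_rejects_asymmetry_and_small_input():
    d = pd.DataFrame([[0, 1], [2, 0]], index=list("ab"), columns=list("ab"))
    with pytest.raises(ValueError):
        nj_tree(pd.DataFrame([[0, 1, 1], [1, 0, 1], [2, 1, 0]], index=list("abc"), columns=list("abc")))
    with pytest.raises(ValueError):
        nj_tree(d)


def test_newick_parses_with_external_reader():
    import io

    from Bio import Phylo

    x = _pop("x", {"a1": 0.9, "a2": 0.1})
    y = _pop("y", {"a1": 0.8, "a2": 0.2})
    z = _pop("z", {"a1": 0.1, "a2": 0.9})
    tree = nj_tree(distance_matrix([x, y, z], ("A",)))
    parsed = Phylo.read(io.StringIO(tree.newick()), "newick")
    assert {t.name for t in parsed.get_terminals()} == {"x", "y", "z"}


# --- bootstrap ---------------------------------------------------------------


def _two_cluster_pops():
    pops = []
    rng = np.random.default_rng(8)
    for i in range(3):
        base = np.array([0.7, 0.2, 0.06, 0.04])
        jit = rng.uniform(-0.02, 0.02, 4)
        v = np.clip(base + jit, 0.01, None)
        v = v / v.sum()
        pops.append(_pop(f"left{i}", dict(zip("abcd", v))))
    for i in range(3):
        base = np.array([0.05, 0.05, 0.2, 0.7])
        jit = rng.uniform(-0.02, 0.02, 4)
        v = np.clip(base + jit, 0.01, None)
        v = v / v.sum()
        pops.append(_pop(f"right{i}", dict(zip("abcd", v))))
    return pops


def test_bootstrap_supports_clean_two_cluster_split():
    pops = _two_cluster_pops()
    tree = bootstrap_support(pops, ("A",), n_reps=100, seed=2)
    split = frozenset({"left0", "left1", "left2"})
    supports = {}

    def walk(node):
        for child, _ in node.children:
            clade = child.leaves()
            if child.support is not None:
                supports[clade] = child.support
            walk(child)

    walk(tree)
    target = [s for clade, s in supports.items() if clade in (split, frozenset(tree.leaves()) - split)]
    assert target and max(target) > 0.95


def test_bootstrap_zero_reps_gives_plain_tree():
    pops = _two_cluster_pops()
    tree = bootstrap_support(pops, ("A",), n_reps=0, seed=0)

    def no_support(node):
        return all(c.support is None and no_support(c) for c, _ in node.children)

    assert no_support(tree)


def test_star_data_has_no_certain_bipartition():
    # symmetric populations (one private majority allele each) are pairwise
    # equidistant: any resolved split is bootstrap-fragile
    names = list("abcde")
    pops = []
    for i, n in enumerate(names):
        freqs = {f"al{j}": (0.6 if j == i else 0.1) for j in range(5)}
        pops.append(_pop(n, freqs))
    d = distance_matrix(pops, ("A",))
    off = d.values[np.triu_indices(5, k=1)]
    assert np.allclose(off, off[0])  # star geometry
    boot = bootstrap_support(pops, ("A",), n_reps=50, seed=3)

    def max_support(node):
        best = 0.0
        for c, _ in node.children:
            if c.support is not None:
                best = max(best, c.support)
            best = max(best, max_support(c))
        return best

    assert max_support(boot) < 1.0


# --- PCA ---------------------------------------------------------------------


def test_pca_two_populations_single_component():
    m = pd.DataFrame([[0.9, 0.1], [0.1, 0.9]], index=["x", "y"], columns=["a", "b"])
    coords, explained = pca(m)
    assert explained[0] == pytest.approx(1.0)


def test_pca_duplicated_populations_coincide():
    pops = _two_cluster_pops()
    m = frequency_matrix(pops + [pops[0]], ("A",))
    m.index = [*[p.population for p in pops], "left0_copy"]
    coords, _ = pca(m)
    assert np.allclose(coords.loc["left0"], coords.loc["left0_copy"])


def test_pca_rank_two_matrix():
    rng = np.random.default_rng(4)
    u = rng.normal(size=(6, 2))
    v = rng.normal(size=(2, 5))
    m = pd.DataFrame(u @ v)
    _, explained = pca(m)
    assert explained[:2].sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(explained) <= 1e-12)


def test_pca_constant_matrix_warns():
    m = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]])
    with pytest.warns(UserWarning):
        coords, explained = pca(m)
    assert explained[0] == 0.0
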