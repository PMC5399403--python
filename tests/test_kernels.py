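import random
from collections import Counter

import numpy as np
import pytest

from pgxlink.graph import PGxGraph
from pgxlink.kernels import (
    KernelConfig,
    Neighborhood,
    check_psd,
    count_bag_of_labels,
    count_neighborhoods,
    count_subtrees,
    count_walks,
    extract_neighborhood,
    kernel_matrix,
    reify,
)
from pgxlink.labels import GENERIC, Label


# -- brute-force oracles (independent of the implementation) ----------


def oracle_walks(n, l, root_constraint=False, include_zero_length=True):
    """Enumerate every directed walk of length 0..l explicitly."""
    out = Counter()

    def rec(v, seq):
        if include_zero_length or len(seq) > 1:
            out[tuple(seq)] += 1
        if len(seq) - 1 < l:
            for w in n.adj[v]:
                rec(w, seq + [n.labels[w]])

    starts = [n.root] if root_constraint else range(len(n.labels))
    for v in starts:
        rec(v, [n.labels[v]])  # zero-length exclusion handled inside rec
    return out


def oracle_subtrees(n, depth, root_constraint=False):
    """Top-down recursive canonicalization of rooted subtrees."""

    def canon(v, h):
        if h == 0:
            return n.labels[v]
        return f"{n.labels[v]}({','.join(sorted(canon(c, h - 1) for c in n.adj[v]))})"

    vertices = [n.root] if root_constraint else range(len(n.labels))
    return Counter(f"{h}|{canon(v, h)}" for h in range(depth + 1) for v in vertices)


def random_reified(rng, max_entities=4, max_edges=5):
    g = PGxGraph()
    n = rng.randint(1, max_entities)
    nodes = [Label("x", f"n{i}") for i in range(n)]
    for node in nodes:
        g.add_node(node, GENERIC)
    preds = [Label("p", c) for c in "abc"]
    n_edges = rng.randint(0, max_edges)
    for _ in range(n_edges):
        g.add_edge(rng.choice(nodes), rng.choice(preds), rng.choice(nodes))
    return g


def whole_graph_neighborhood(rg, root_idx=0):
    return Neighborhood(list(rg.labels), [list(a) for a in rg.adj], root=root_idx)


# -- reification -------------------------------------------------------


def test_reify_single_edge():
    g = PGxGraph()
    a, b = Label("x", "a"), Label("x", "b")
    g.add_node(a, GENERIC)
    g.add_node(b, GENERIC)
    g.add_edge(a, Label("p", "p"), b)
    rg = reify(g)
    assert sorted(rg.labels) == ["p:p", "x:a", "x:b"]
    assert rg.n_edges == 2


def test_reify_empty():
    rg = reify(PGxGraph())
    assert rg.n_vertices == 0 and rg.n_edges == 0


def test_reify_counting_law_random_multigraph():
    rng = random.Random(0)
    for _ in range(20):
        g = random_reified(rng, max_entities=5, max_edges=15)
        rg = reify(g)
        assert rg.n_vertices == g.n_nodes + g.n_edges
        assert rg.n_edges == 2 * g.n_edges


# -- neighborhoods -----------------------------------------------------


def _cycle3_reified():
    """Already-labeled 3-cycle a->b->c->a (treated as reified)."""
    labels = ["a", "b", "c"]
    adj = [[1], [2], [0]]
    return labels, adj


def test_isolated_root_neighborhood():
    g = PGxGraph()
    a = Label("x", "a")
    g.add_node(a, GENERIC)
    rg = reify(g)
    for mode in ("subgraph", "tree"):
        n = extract_neighborhood(rg, a, KernelConfig(depth=3, neighborhood=mode))
        assert n.labels == ["x:a"]


def test_cycle_subgraph_vs_tree_unfolding():
    labels, adj = _cycle3_reified()
    rg_like = Neighborhood(labels, adj, root=0)

    class FakeRG:
        def __init__(self):
            self.labels = labels
            self.adj = adj
            self.index = {Label("x", l): i for i, l in enumerate(labels)}

    rg = FakeRG()
    sub = extract_neighborhood(rg, Label("x", "a"), KernelConfig(depth=3, neighborhood="subgraph"))
    assert sorted(sub.labels) == ["a", "b", "c"]
    tree = extract_neighborhood(rg, Label("x", "a"), KernelConfig(depth=3, neighborhood="tree"))
    assert sorted(tree.labels) == ["a", "a", "b", "c"]  # cycle reopened as path
    assert count_bag_of_labels(tree) == Counter({"a": 2, "b": 1, "c": 1})


def test_star_neighborhood_depth_one():
    g = PGxGraph()
    hub = Label("x", "hub")
    g.add_node(hub, GENERIC)
    for i in range(4):
        g.add_edge(hub, Label("p", "p"), Label("x", f"leaf{i}"))
    rg = reify(g)
    for mode in ("subgraph", "tree"):
        n = extract_neighborhood(rg, hub, KernelConfig(depth=1, neighborhood=mode))
        assert len(n.labels) == 5  # root + 4 reified predicate occurrences


def test_missing_root_errors():
    rg = reify(PGxGraph())
    with pytest.raises(ValueError, match="not in graph"):
        extract_neighborhood(rg, Label("x", "nope"), KernelConfig())


def test_tree_unfolding_cap():
    labels, adj = _cycle3_reified()

    class FakeRG:
        def __init__(self):
            self.labels = labels
            self.adj = adj
            self.index = {Label("x", "a"): 0}

    with pytest.raises(ValueError, match="occurrences"):
        extract_neighborhood(
            FakeRG(), Label("x", "a"), KernelConfig(depth=50, neighborhood="tree", max_tree_occurrences=10)
        )


def test_tree_equals_subgraph_on_out_tree():
    # rooted out-tree: unique paths, so unfolding adds nothing
    g = PGxGraph()
    root = Label("x", "r")
    g.add_node(root, GENERIC)
    g.add_edge(root, Label("p", "p"), Label("x", "l1"))
    g.add_edge(root, Label("p", "q"), Label("x", "l2"))
    rg = reify(g)
    sub = extract_neighborhood(rg, root, KernelConfig(depth=4, neighborhood="subgraph"))
    tree = extract_neighborhood(rg, root, KernelConfig(depth=4, neighborhood="tree"))
    assert Counter(sub.labels) == Counter(tree.labels)
    for l in (0, 1, 2):
        assert count_walks(sub, l) == count_walks(tree, l)
        assert count_subtrees(sub, l) == count_subtrees(tree, l)


# -- substructure counts ----------------------------------------------


def test_bag_of_labels_examples():
    single = Neighborhood(["r"], [[]], 0)
    assert count_bag_of_labels(single) == Counter({"r": 1})
    path = Neighborhood(["a", "p", "b"], [[1], [2], []], 0)
    assert count_bag_of_labels(path) == Counter({"a": 1, "p": 1, "b": 1})


def test_walks_on_reified_path():
    path = Neighborhood(["a", "p", "b"], [[1], [2], []], 0)
    expected = Counter(
        {("a",): 1, ("p",): 1, ("b",): 1, ("a", "p"): 1, ("p", "b"): 1, ("a", "p", "b"): 1}
    )
    assert count_walks(path, 2) == expected
    rooted = count_walks(path, 2, root_constraint=True)
    assert rooted == Counter({("a",): 1, ("a", "p"): 1, ("a", "p", "b"): 1})


def test_walk_single_vertex():
    n = Neighborhood(["v"], [[]], 0)
    assert count_walks(n, 2) == Counter({("v",): 1})


def test_subtree_leaf_counts_one_per_iteration():
    n = Neighborhood(["v"], [[]], 0)
    c = count_subtrees(n, 3)
    assert sum(c.values()) == 4
    assert all(v == 1 for v in c.values())


def test_subtree_child_order_free():
    t1 = Neighborhood(["r", "x", "y"], [[1, 2], [], []], 0)
    t2 = Neighborhood(["r", "y", "x"], [[1, 2], [], []], 0)
    assert count_subtrees(t1, 2) == count_subtrees(t2, 2)


def test_counts_match_bruteforce_oracles_random_graphs():
    rng = random.Random(42)
    for trial in range(60):
        g = random_reified(rng)
        rg = reify(g)
        if rg.n_vertices == 0 or rg.n_vertices > 12:
            continue
        n = whole_graph_neighborhood(rg, root_idx=rng.randrange(rg.n_vertices))
        for l in (0, 1, 2, 3, 4):
            assert count_walks(n, l) == oracle_walks(n, l)
            assert count_walks(n, l, root_constraint=True) == oracle_walks(
                n, l, root_constraint=True
            )
        for d in (0, 1, 2, 3):
            assert count_subtrees(n, d) == oracle_subtrees(n, d)
            assert count_subtrees(n, d, root_constraint=True) == oracle_subtrees(
                n, d, root_constraint=True
            )


def test_root_constrained_counts_are_submultiset():
    rng = random.Random(7)
    for _ in range(20):
        g = random_reified(rng)
        rg = reify(g)
        if rg.n_vertices == 0:
            continue
        n = whole_graph_neighborhood(rg)
        full = count_walks(n, 3)
        rooted = count_walks(n, 3, root_constraint=True)
        assert all(full[k] >= v for k, v in rooted.items())
        fs = count_subtrees(n, 2)
        rs = count_subtrees(n, 2, root_constraint=True)
        assert all(fs[k] >= v for k, v in rs.items())


def test_min_frequency_zero_is_identity_and_monotone_support():
    rng = random.Random(11)
    neighborhoods = []
    for _ in range(6):
        g = random_reified(rng)
        rg = reify(g)
        if rg.n_vertices:
            neighborhoods.append(whole_graph_neighborhood(rg))
    base_cfg = KernelConfig(substructure="bag_of_labels", min_frequency=0)
    base = count_neighborhoods(neighborhoods, base_cfg)
    identity = [count_bag_of_labels(n) for n in neighborhoods]
    assert base == identity
    prev = base
    for mf in (1, 2, 4, 8):
        cur = count_neighborhoods(
            neighborhoods, KernelConfig(substructure="bag_of_labels", min_frequency=mf)
        )
        for c_prev, c_cur in zip(prev, cur):
            assert set(c_cur) <= set(c_prev)
        prev = cur


# -- kernel matrix -----------------------------------------------------


def test_kernel_identical_vectors_normalize_to_one():
    c = Counter({"a": 2, "b": 1})
    K = kernel_matrix([c, Counter(c)], normalize=True)
    assert np.allclose(K, 1.0)


def test_kernel_disjoint_support_is_zero():
    K = kernel_matrix([Counter({"a": 1}), Counter({"b": 3})], normalize=True)
    assert K[0, 1] == 0.0 and K[0, 0] == 1.0


def test_kernel_empty_vector_normalized_diagonal_zero():
    K = kernel_matrix([Counter({"a": 1}), Counter()], normalize=True)
    assert K[1, 1] == 0.0


def test_kernel_matches_dense_oracle_and_is_psd():
    rng = np.random.default_rng(5)
    vocab = [f"k{i}" for i in range(30)]
    counts = []
    for _ in range(5):
        c = Counter()
        for j in rng.choice(30, size=8, replace=False):
            c[vocab[j]] = int(rng.integers(1, 5))
        counts.append(c)
    K = kernel_matrix(counts, normalize=False)
    dense = np.zeros((5, 30))
    for i, c in enumerate(counts):
        for k, v in c.items():
            dense[i, vocab.index(k)] = v
    assert np.allclose(K, dense @ dense.T)
    assert np.allclose(K, K.T, atol=1e-12)
    assert check_psd(K) >= -1e-9
    Kn = kernel_matrix(counts, normalize=True)
    assert np.allclose(np.diag(Kn), 1.0)
    assert check_psd(Kn) >= -1e-9


def test_kernel_config_validation():
    with pytest.raises(ValueError):
        KernelConfig(depth=0)
    with pytest.raises(ValueError):
        KernelConfig(substructure="loops")
    with pytest.raises(ValueError):
        KernelConfig(neighborhood="ball")
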