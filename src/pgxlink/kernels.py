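"""From-scratch substructure-counting graph kernels over pair nodes.

The RDF-style graph is first *reified*: every labeled edge (u, p, v)
becomes u -> node(p) -> v, so predicates take part in counting exactly
like vertices. Around each instance (gene-drug pair node) a depth-bounded
neighborhood is extracted, either as a subgraph (each vertex once, cycles
kept) or as a tree unfolding (revisited vertices repeated). Within the
neighborhood one of three substructure families is counted:

* bag of labels — the multiset of vertex labels;
* walks — label sequences along directed walks up to a length, counted
  with multiplicity (number of realizations);
* subtrees — Weisfeiler-Lehman-style iteratively refined rooted-subtree
  labels up to a depth.

Sparse pattern-count vectors are compared by dot products, yielding a
symmetric positive semidefinite kernel matrix for an SVM.

Depth ``d`` and substructure size ``l`` are counted in edges *on the
reified graph*: a depth of 4 spans two original predicates plus the
entities between them.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp

from .graph import PGxGraph
from .labels import PRED_HAS_CLASS, Label

RARE = "_"  # replacement token for labels below the global minimum frequency


@dataclass(frozen=True)
class KernelConfig:
    depth: int = 4
    substructure: str = "subtrees"  # bag_of_labels | walks | subtrees
    neighborhood: str = "tree"  # subgraph | tree
    root_constraint: bool = False
    substructure_size: int = 4  # max walk length / subtree depth
    min_frequency: int = 8  # labels used fewer times than this do not generalize
    normalize: bool = True
    include_zero_length_walks: bool = True
    max_tree_occurrences: int = 100_000

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.substructure_size < 0 or self.min_frequency < 0:
            raise ValueError("substructure_size and min_frequency must be >= 0")
        if self.substructure not in ("bag_of_labels", "walks", "subtrees"):
            raise ValueError(f"unknown substructure {self.substructure!r}")
        if self.neighborhood not in ("subgraph", "tree"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")


class ReifiedGraph:
    """Vertex-labeled digraph in which former edges are labeled vertices."""

    def __init__(self, labels: List[str], adj: List[List[int]], index: Dict[Label, int]):
        self.labels = labels
        self.adj = adj
        self.index = index  # original resource -> vertex id

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self.adj)


def reify(g: PGxGraph, exclude_predicates: Iterable[Label] = ()) -> ReifiedGraph:
    """Turn each edge occurrence (u, p, v) into u -> node(p) -> v.

    The result has |V| + |E| vertices and 2|E| edges. ``exclude_predicates``
    drops edges outright (used to keep class-membership edges out of
    kernel neighborhoods, where they would leak training labels).
    """
    excluded = set(exclude_predicates)
    labels: List[str] = []
    adj: List[List[int]] = []
    index: Dict[Label, int] = {}
    for node in sorted(g.node_types):
        index[node] = len(labels)
        labels.append(str(node))
        adj.append([])
    for e in sorted(g.edges):
        if e.predicate in excluded:
            continue
        mid = len(labels)
        labels.append(str(e.predicate))
        adj.append([index[e.obj]])
        adj[index[e.subject]].append(mid)
    return ReifiedGraph(labels, adj, index)


@dataclass
class Neighborhood:
    """Depth-bounded region around a root, as a local vertex-labeled
    digraph. In tree mode vertices are *occurrences* (repetition allowed);
    in subgraph mode each reified vertex appears once."""

    labels: List[str]
    adj: List[List[int]]
    root: int = 0
    is_tree: bool = False

    @property
    def n_vertices(self) -> int:
        return len(self.labels)


def extract_neighborhood(rg: ReifiedGraph, root: Label, cfg: KernelConfig) -> Neighborhood:
    if root not in rg.index:
        raise ValueError(f"root {root} not in graph")
    r = rg.index[root]
    if cfg.neighborhood == "subgraph":
        return _subgraph_neighborhood(rg, r, cfg.depth)
    return _tree_neighborhood(rg, r, cfg.depth, cfg.max_tree_occurrences)


def _subgraph_neighborhood(rg: ReifiedGraph, r: int, depth: int) -> Neighborhood:
    dist = {r: 0}
    queue = deque([r])
    while queue:
        u = queue.popleft()
        if dist[u] == depth:
            continue
        for v in rg.adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    kept = sorted(dist)
    local = {v: i for i, v in enumerate(kept)}
    labels = [rg.labels[v] for v in kept]
    adj = [[local[w] for w in rg.adj[v] if w in local] for v in kept]
    return Neighborhood(labels, adj, root=local[r], is_tree=False)


def _sorted_children(rg: ReifiedGraph, u: int) -> List[int]:
    # deterministic order: by label, then vertex id
    return sorted(rg.adj[u], key=lambda v: (rg.labels[v], v))


def _tree_neighborhood(rg: ReifiedGraph, r: int, depth: int, cap: int) -> Neighborhood:
    labels: List[str] = [rg.labels[r]]
    adj: List[List[int]] = [[]]
    stack = [(0, r, 0)]  # (occurrence id, reified vertex, depth)
    while stack:
        occ, u, d = stack.pop()
        if d == depth:
            continue
        for v in _sorted_children(rg, u):
            child = len(labels)
            if child > cap:
                raise ValueError(
                    f"tree unfolding exceeds {cap} occurrences; raise max_tree_occurrences "
                    "or lower the depth"
                )
            labels.append(rg.labels[v])
            adj.append([])
            adj[occ].append(child)
            stack.append((child, v, d + 1))
    return Neighborhood(labels, adj, root=0, is_tree=True)


# -- substructure counting --------------------------------------------


def count_bag_of_labels(
    n: Neighborhood, min_frequency: int = 0, global_frequencies: Optional[Mapping[str, int]] = None
) -> Counter:
    """Multiset of vertex-occurrence labels; labels whose global frequency
    falls below ``min_frequency`` are dropped."""
    freq = global_frequencies if global_frequencies is not None else Counter(n.labels)
    return Counter(l for l in n.labels if freq.get(l, 0) >= min_frequency)


def count_walks(
    n: Neighborhood,
    l: int,
    root_constraint: bool = False,
    include_zero_length: bool = True,
) -> Counter:
    """Count label sequences of directed walks of length 0..l, with
    multiplicity (one count per realization)."""
    if l < 0:
        raise ValueError("l must be >= 0")
    counts: Counter = Counter()
    starts = [n.root] if root_constraint else range(n.n_vertices)
    frontier: Counter = Counter({(v, (n.labels[v],)): 1 for v in starts})
    for length in range(l + 1):
        if length > 0 or include_zero_length:
            for (_, seq), c in frontier.items():
                counts[seq] += c
        if length == l:
            break
        nxt: Counter = Counter()
        for (v, seq), c in frontier.items():
            for w in n.adj[v]:
                nxt[(w, seq + (n.labels[w],))] += c
        frontier = nxt
    return counts


def count_subtrees(n: Neighborhood, depth: int, root_constraint: bool = False) -> Counter:
    """Iterative label refinement (Weisfeiler-Lehman style).

    At iteration 0 a vertex's refined label is its own label; at
    iteration h it is ``label(own, sorted multiset of children's
    iteration-(h-1) labels)``. All refined labels of iterations 0..depth
    are counted (root occurrence only under the root constraint); keys
    are canonical strings tagged with the iteration number.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    refined = list(n.labels)
    counts: Counter = Counter()
    vertices = [n.root] if root_constraint else range(n.n_vertices)
    for h in range(depth + 1):
        if h > 0:
            refined = [
                f"{n.labels[v]}({','.join(sorted(refined[c] for c in n.adj[v]))})"
                for v in range(n.n_vertices)
            ]
        for v in vertices:
            counts[f"{h}|{refined[v]}"] += 1
    return counts


def _relabel_rare(n: Neighborhood, freq: Mapping[str, int], min_frequency: int) -> Neighborhood:
    labels = [l if freq.get(l, 0) >= min_frequency else RARE for l in n.labels]
    return Neighborhood(labels, n.adj, n.root, n.is_tree)


def count_neighborhoods(
    neighborhoods: Sequence[Neighborhood], cfg: KernelConfig
) -> List[Counter]:
    """Apply the configured substructure count to a dataset of instance
    neighborhoods, with the minimum-frequency filter computed globally
    over all of them (per-instance filtering would break comparability)."""
    freq: Counter = Counter()
    for n in neighborhoods:
        freq.update(n.labels)
    out = []
    for n in neighborhoods:
        if cfg.substructure == "bag_of_labels":
            out.append(count_bag_of_labels(n, cfg.min_frequency, freq))
            continue
        if cfg.min_frequency > 0:
            n = _relabel_rare(n, freq, cfg.min_frequency)
        if cfg.substructure == "walks":
            out.append(
                count_walks(
                    n,
                    cfg.substructure_size,
                    cfg.root_constraint,
                    cfg.include_zero_length_walks,
                )
            )
        else:
            out.append(count_subtrees(n, cfg.substructure_size, cfg.root_constraint))
    return out


# -- kernel matrix -----------------------------------------------------


def counts_to_sparse(counts: Sequence[Counter]) -> Tuple[sp.csr_matrix, List]:
    vocab: Dict = {}
    rows, cols, data = [], [], []
    for i, c in enumerate(counts):
        for pattern, v in c.items():
            j = vocab.setdefault(pattern, len(vocab))
            rows.append(i)
            cols.append(j)
            data.append(float(v))
    X = sp.csr_matrix((data, (rows, cols)), shape=(len(counts), max(len(vocab), 1)))
    patterns = sorted(vocab, key=vocab.get)
    return X, patterns


def kernel_matrix(counts: Sequence[Counter], normalize: bool = True) -> np.ndarray:
    """Pairwise dot products of sparse pattern-count vectors; optionally
    cosine-normalized (all-zero vectors yield 0)."""
    if not counts:
        raise ValueError("need at least one count vector")
    X, _ = counts_to_sparse(counts)
    K = np.asarray((X @ X.T).todense(), dtype=float)
    K = (K + K.T) / 2.0
    if normalize:
        d = np.sqrt(np.diag(K))
        with np.errstate(divide="ignore", invalid="ignore"):
            K = K / np.outer(d, d)
        K[~np.isfinite(K)] = 0.0
        np.fill_diagonal(K, np.where(d > 0, 1.0, 0.0))
    return K


def check_psd(K: np.ndarray, tol: float = 1e-9) -> float:
    """Smallest eigenvalue; raises if the matrix is not PSD within tol."""
    if not np.allclose(K, K.T, atol=1e-12):
        raise ValueError("kernel matrix is not symmetric")
    w = np.linalg.eigvalsh(K)
    if w[0] < -tol:
        raise ValueError(f"kernel matrix is not PSD (min eigenvalue {w[0]:.3e})")
    return float(w[0])


# -- pipeline helper ---------------------------------------------------


def pair_kernel(
    g: PGxGraph, pair_nodes: Sequence[Label], cfg: KernelConfig = KernelConfig()
) -> np.ndarray:
    """Kernel matrix over gene-drug pair nodes of an augmented graph.

    Class-membership edges are excluded from the reified graph so the
    kernel never sees training labels.
    """
    rg = reify(g, exclude_predicates={PRED_HAS_CLASS})
    neighborhoods = [extract_neighborhood(rg, p, cfg) for p in pair_nodes]
    counts = count_neighborhoods(neighborhoods, cfg)
    return kernel_matrix(counts, cfg.normalize)
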