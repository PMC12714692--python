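"""Shared fixtures and independent oracles.

Oracles here deliberately avoid the code paths they check: betweenness is
recomputed by exhaustive simple-path enumeration, eigenvector centrality by
dense eigendecomposition, hypergeometric tails by direct combinatorial
summation, and the network constructor by a quadruple loop over set pairs
and gene pairs.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from genecontext import GeneSet, TopicNetwork, generate_benchmark_graph


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_betweenness(g: nx.Graph) -> dict:
    """Betweenness by exhaustive enumeration of all simple paths (<=~8 nodes).

    Each unordered pair contributes once; the contribution of node v is the
    fraction of that pair's shortest paths passing through v.
    """
    adj = {v: set(g[v]) for v in g.nodes}

    def all_simple_paths(s, t):
        out = []
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                out.append(path)
                continue
            for nbr in adj[node]:
                if nbr not in path:
                    stack.append((nbr, path + [nbr]))
        return out

    btw = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        paths = all_simple_paths(s, t)
        if not paths:
            continue
        d = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == d]
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            btw[v] += through / len(shortest)
    return btw


def dense_eigenvector_centrality(g: nx.Graph) -> dict:
    """Dominant adjacency eigenvector via numpy.linalg.eigh, max-normalised."""
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    evals, evecs = np.linalg.eigh(a)
    vec = np.abs(evecs[:, np.argmax(evals)])
    vec /= vec.max()
    return dict(zip(nodes, vec))


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / math.comb(N, n)


def clique_union_oracle(sets: list[GeneSet]) -> set[frozenset]:
    """Quadruple-loop edge enumeration over set pairs and gene pairs."""
    edges = set()
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            gi, gj = set(sets[i].genes), set(sets[j].genes)
            for a in gi:
                for b in gi:
                    if a < b and a in gj and b in gj:
                        edges.add(frozenset((a, b)))
    return edges


def least_squares_slope(x, y) -> float:
    """Closed-form simple-regression slope."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    xm = sum(x) / len(x)
    ym = sum(y) / len(y)
    sxy = sum((a - xm) * (b - ym) for a, b in zip(x, y))
    sxx = sum((a - xm) ** 2 for a in x)
    return sxy / sxx


def random_connected_graph(rng: np.random.Generator, n_max: int = 7) -> nx.Graph:
    """Small random connected graph (spanning tree + random extra edges)."""
    n = int(rng.integers(2, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    order = list(rng.permutation(n))
    for i in range(1, n):
        g.add_edge(order[i], order[int(rng.integers(i))])
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        u, v = rng.integers(n), rng.integers(n)
        if u != v:
            g.add_edge(int(u), int(v))
    return g


def as_network(g: nx.Graph, topic: int = 0) -> TopicNetwork:
    return TopicNetwork(topic=topic, graph=nx.relabel_nodes(g, str))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def path4() -> TopicNetwork:
    return generate_benchmark_graph("path", n=4)


@pytest.fixture
def star5() -> TopicNetwork:
    return generate_benchmark_graph("star", n=5)


@pytest.fixture
def k4() -> TopicNetwork:
    return generate_benchmark_graph("complete", n=4)


@pytest.fixture
def k5() -> TopicNetwork:
    return generate_benchmark_graph("complete", n=5)


@pytest.fixture
def bridged_triangles() -> TopicNetwork:
    return generate_benchmark_graph("two_triangles", bridged=True)


@pytest.fixture
def disjoint_triangles() -> TopicNetwork:
    return generate_benchmark_graph("two_triangles", bridged=False)
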