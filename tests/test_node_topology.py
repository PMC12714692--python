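"""Per-gene centralities, local fractal dimension, perturbation robustness."""

import math

import networkx as nx
import numpy as np
import pytest

from genecontext import (
    GeneSet,
    PerturbationConfig,
    betweenness_centrality,
    compute_node_metrics,
    eigenvector_centrality,
    generate_benchmark_graph,
    geneset_topology_score,
    local_fractal_dimension,
    perturb_and_score,
    rescale_unit_interval,
)
from genecontext.graph_build import TopicNetwork

from conftest import (
    as_network,
    brute_force_betweenness,
    dense_eigenvector_centrality,
    least_squares_slope,
    random_connected_graph,
)


class TestBetweenness:
    def test_complete_graph_all_zero(self, k4):
        assert set(betweenness_centrality(k4).values()) == {0.0}

    def test_star_center_closed_form(self, star5):
        btw = betweenness_centrality(star5)
        center = max(btw, key=btw.get)
        assert btw[center] == pytest.approx(math.comb(4, 2))
        assert all(v == 0.0 for g, v in btw.items() if g != center)

    def test_path_interior_nodes(self, path4):
        btw = betweenness_centrality(path4)
        oracle = brute_force_betweenness(path4.graph)
        assert btw == pytest.approx(oracle)
        assert sorted(btw.values()) == [0.0, 0.0, 2.0, 2.0]

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(40):
            net = as_network(random_connected_graph(rng))
            btw = betweenness_centrality(net)
            oracle = brute_force_betweenness(net.graph)
            for gene in btw:
                assert btw[gene] == pytest.approx(oracle[gene], abs=1e-9)


class TestEigenvector:
    def test_complete_graph_all_ones(self, k4):
        assert all(
            v == pytest.approx(1.0, abs=1e-9)
            for v in eigenvector_centrality(k4).values()
        )

    def test_path3_closed_form(self):
        net = generate_benchmark_graph("path", n=3)
        vec = eigenvector_centrality(net)
        assert vec["n1"] == pytest.approx(1.0, abs=1e-9)
        assert vec["n0"] == pytest.approx(1 / math.sqrt(2), abs=1e-8)
        assert vec["n2"] == pytest.approx(1 / math.sqrt(2), abs=1e-8)

    def test_star_leaves_closed_form(self, star5):
        vec = eigenvector_centrality(star5)
        center = max(vec, key=vec.get)
        assert vec[center] == pytest.approx(1.0)
        for g, v in vec.items():
            if g != center:
                assert v == pytest.approx(1 / math.sqrt(4), abs=1e-8)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(43)
        for _ in range(40):
            net = as_network(random_connected_graph(rng))
            vec = eigenvector_centrality(net)
            oracle = dense_eigenvector_centrality(net.graph)
            for gene in vec:
                assert vec[gene] == pytest.approx(oracle[gene], abs=1e-9)

    def test_non_convergence_names_max_iter(self, path4):
        with pytest.raises(RuntimeError, match="max_iter=1"):
            eigenvector_centrality(path4, tol=1e-15, max_iter=1)


class TestLocalFractalDimension:
    def test_reported_ball_profile_slope(self):
        # neighbourhood growth profile 2 / 29 / 373 at radii 1 / 2 / 3:
        # a chain of stars realises these cumulative ball counts exactly
        g = nx.Graph()
        g.add_edges_from([("c", "a"), ("c", "b")])
        for i in range(27):
            g.add_edge("a", f"x{i}")
        for i in range(344):
            g.add_edge("x0", f"y{i}")
        net = TopicNetwork(topic=0, graph=g)
        dist = nx.single_source_shortest_path_length(g, "c")
        profile = [sum(1 for d in dist.values() if 0 < d <= r) for r in (1, 2, 3)]
        assert profile == [2, 29, 373]
        lfd = local_fractal_dimension(net, "c")
        expect = least_squares_slope(
            [math.log(r) for r in (1, 2, 3)],
            [math.log(m) for m in (2, 29, 373)],
        )
        assert lfd == pytest.approx(expect, abs=1e-9)

    def test_star_leaf_two_point_slope(self):
        net = generate_benchmark_graph("star", n=7)
        leaf = "n1"
        # from a leaf: 1 node at r=1 (the hub), all n-1 others by r=2
        assert local_fractal_dimension(net, leaf) == pytest.approx(
            math.log(6) / math.log(2), abs=1e-9
        )

    def test_complete_graph_degenerate_zero(self, k5):
        assert local_fractal_dimension(k5, "n0") == 0.0

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(47)
        g = random_connected_graph(rng)
        net = as_network(g)
        mapping = {str(v): f"z{v}" for v in g.nodes}
        relabeled = TopicNetwork(topic=0, graph=nx.relabel_nodes(net.graph, mapping))
        for v in net.graph.nodes:
            assert local_fractal_dimension(net, v) == pytest.approx(
                local_fractal_dimension(relabeled, mapping[v]), abs=1e-12
            )

    def test_tree_center_lfd_increases_with_branching(self):
        slopes = []
        for k in (2, 3, 4):
            net = generate_benchmark_graph("k_ary_tree", k=k, depth=5)
            slopes.append(local_fractal_dimension(net, "n0"))
        assert slopes == sorted(slopes)

    def test_missing_gene_rejected(self, k4):
        with pytest.raises(KeyError):
            local_fractal_dimension(k4, "absent")


def _reference_perturbation(net, cfg):
    """Independent re-run of the documented rewiring procedure with
    networkx betweenness, replaying the same random stream."""
    nodes = sorted(net.graph.nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    base = sorted(
        (min(idx[a], idx[b]), max(idx[a], idx[b])) for a, b in net.graph.edges
    )
    n_rw = max(1, int(math.floor(cfg.rewire_rate * len(base) + 0.5)))
    rng = np.random.default_rng(cfg.seed)
    samples = []
    for _ in range(cfg.n_iter):
        edges = list(base)
        eset = set(edges)
        for _ in range(n_rw):
            pos = int(rng.integers(len(edges)))
            removed = edges[pos]
            edges[pos] = edges[-1]
            edges.pop()
            eset.remove(removed)
            pair = None
            if len(eset) < n * (n - 1) // 2:
                for _ in range(200):
                    i, j = int(rng.integers(n)), int(rng.integers(n))
                    if i == j:
                        continue
                    cand = (i, j) if i < j else (j, i)
                    if cand not in eset:
                        pair = cand
                        break
                else:
                    non_edges = [
                        (i, j)
                        for i in range(n)
                        for j in range(i + 1, n)
                        if (i, j) not in eset
                    ]
                    pair = non_edges[int(rng.integers(len(non_edges)))]
            if pair is None:
                pair = removed
            edges.append(pair)
            eset.add(pair)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)
        btw = nx.betweenness_centrality(g, normalized=False)
        samples.append([btw[i] for i in range(n)])
    var = np.var(np.array(samples), axis=0, ddof=0)
    return dict(zip(nodes, var))


class TestPerturbation:
    def test_rewire_count_floor_at_one(self):
        cfg = PerturbationConfig(rewire_rate=0.001)
        assert cfg.n_rewired(248) == 1
        assert cfg.n_rewired(1) == 1
        assert cfg.n_rewired(2531) == 3

    def test_complete_graph_forced_restoration(self, k5):
        var = perturb_and_score(k5, PerturbationConfig(n_iter=50, seed=1))
        assert set(var.values()) == {0.0}

    def test_fixed_seed_bit_reproducible(self, bridged_triangles):
        cfg = PerturbationConfig(n_iter=30, seed=5)
        v1 = perturb_and_score(bridged_triangles, cfg)
        v2 = perturb_and_score(bridged_triangles, cfg)
        assert v1 == v2

    def test_matches_independent_procedure_rerun(self, bridged_triangles):
        cfg = PerturbationConfig(n_iter=3, seed=11)
        var = perturb_and_score(bridged_triangles, cfg)
        ref = _reference_perturbation(bridged_triangles, cfg)
        for gene in var:
            assert var[gene] == pytest.approx(ref[gene], abs=1e-9)

    def test_igraph_betweenness_matches_networkx_convention(self, path4, star5):
        import igraph as ig

        for net in (path4, star5):
            nodes = sorted(net.graph.nodes)
            idx = {g: i for i, g in enumerate(nodes)}
            edges = [(idx[a], idx[b]) for a, b in net.graph.edges]
            g = ig.Graph(n=len(nodes), edges=edges, directed=False)
            nx_btw = nx.betweenness_centrality(net.graph, normalized=False)
            for gene, i in idx.items():
                assert g.betweenness(directed=False)[i] == pytest.approx(
                    nx_btw[gene], abs=1e-12
                )

    def test_empty_edge_set_rejected(self):
        net = TopicNetwork(topic=0, graph=nx.empty_graph(3))
        with pytest.raises(ValueError):
            perturb_and_score(net, PerturbationConfig(n_iter=1))


class TestRescale:
    def test_linear_example(self):
        out = rescale_unit_interval({"a": 1.0, "b": 3.0, "c": 5.0})
        assert out == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_constant_maps_to_half(self):
        out = rescale_unit_interval({"a": 2.0, "b": 2.0})
        assert set(out.values()) == {0.5}

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(53)
        vals = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=30))}
        scaled = rescale_unit_interval(vals)
        order = sorted(vals, key=vals.get)
        assert order == sorted(scaled, key=scaled.get)

    def test_affine_invariance(self):
        rng = np.random.default_rng(59)
        vals = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=20))}
        base = rescale_unit_interval(vals)
        shifted = rescale_unit_interval(
            {k: 3.7 * v + 11.0 for k, v in vals.items()}
        )
        for k in vals:
            assert shifted[k] == pytest.approx(base[k], abs=1e-12)

    def test_open_interval_variant_strictly_inside(self):
        out = rescale_unit_interval({"a": 0.0, "b": 1.0}, open_interval=True)
        assert 0 < min(out.values()) and max(out.values()) < 1


@pytest.fixture(scope="module")
def table():
    net = generate_benchmark_graph("two_triangles", bridged=True)
    return compute_node_metrics(net, PerturbationConfig(n_iter=20, seed=2))


class TestNodeMetricsTable:
    def test_all_rescaled_columns_in_unit_interval(self, table):
        for col in table.columns:
            if col.endswith("_scaled"):
                assert table[col].between(0, 1).all()

    def test_one_row_per_node(self, table):
        assert len(table) == 6

    def test_geneset_score_single_gene(self, table):
        gs = GeneSet("S", "", ("n2",))
        rec = geneset_topology_score(table, gs, "betweenness_scaled")
        assert rec["score"] == pytest.approx(table.loc["n2", "betweenness_scaled"])
        assert rec["n_overlap"] == 1

    def test_geneset_score_disjoint_set_flagged(self, table):
        gs = GeneSet("S", "", ("absent1", "absent2"))
        rec = geneset_topology_score(table, gs, "lfd_scaled")
        assert rec["score"] is None and rec["coverage"] == 0.0

    def test_geneset_score_mean_matches_hand_arithmetic(self, table):
        genes = ("n0", "n1", "n3", "n4", "n5")
        gs = GeneSet("S", "", genes)
        rec = geneset_topology_score(table, gs, "eigenvector_scaled")
        expect = np.mean([table.loc[g, "eigenvector_scaled"] for g in genes])
        assert rec["score"] == pytest.approx(float(expect))
        assert rec["coverage"] == pytest.approx(5 / 6)
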