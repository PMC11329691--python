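import numpy as np
import pytest

from whisker_connectome import (
    BinaryConnectome,
    ablation_permutation_test,
    detect_hubs,
    er_null,
    nodal_metrics,
    small_world_verdict,
)
from whisker_connectome.errors import DegenerateInputError
from whisker_connectome.graphs import NODAL_METRICS, permutation_pvalue

from oracles import brute_nodal_metrics, exhaustive_permutation_pvalue


def _bc(adj, nodes=None):
    adj = np.asarray(adj, dtype=int)
    n = adj.shape[0]
    nodes = nodes or [f"n{i}" for i in range(n)]
    return BinaryConnectome(nodes=nodes, adjacency=adj, measured=np.ones(n, dtype=bool))


def _star(n_leaves=4):
    adj = np.zeros((n_leaves + 1, n_leaves + 1), dtype=int)
    adj[0, 1:] = 1
    return _bc(adj, nodes=["center"] + [f"leaf{i}" for i in range(n_leaves)])


class TestNodalMetrics:
    def test_three_cycle_symmetry(self):
        adj = [[0, 1, 0], [0, 0, 1], [1, 0, 0]]
        rep = nodal_metrics(_bc(adj))
        assert (rep.nodal["in_degree"] == 1).all()
        assert (rep.nodal["out_degree"] == 1).all()
        assert (rep.nodal["degree_centrality"] == 2).all()
        assert rep.nodal["betweenness"].nunique() == 1

    def test_star_worked_example(self):
        rep = nodal_metrics(_star())
        dc = rep.nodal["degree_centrality"]
        assert list(dc) == [4, 1, 1, 1, 1]
        assert rep.global_mean["degree_centrality"] == pytest.approx(1.6)
        assert rep.global_sd["degree_centrality"] == pytest.approx(1.2)
        assert rep.hub_set == {"center"}

    def test_complete_graph_saturates(self):
        adj = 1 - np.eye(4, dtype=int)
        rep = nodal_metrics(_bc(adj))
        assert (rep.nodal["clustering"] == 1).all()
        assert (rep.nodal["shortest_path"] == 1).all()
        assert (rep.nodal["efficiency"] == 1).all()

    def test_isolated_node_zeroes(self):
        adj = np.zeros((3, 3), dtype=int)
        adj[0, 1] = 1
        rep = nodal_metrics(_bc(adj))
        for m in ("clustering", "efficiency", "betweenness", "shortest_path"):
            assert rep.nodal.loc["n2", m] == 0.0

    def test_empty_graph_rejected(self):
        with pytest.raises(DegenerateInputError):
            nodal_metrics(_bc(np.zeros((0, 0), dtype=int), nodes=[]))

    def test_degree_sum_identity(self, rng):
        adj = (rng.random((12, 12)) < 0.3).astype(int)
        np.fill_diagonal(adj, 0)
        rep = nodal_metrics(_bc(adj))
        assert rep.nodal["degree_centrality"].sum() == 2 * adj.sum()

    def test_normalized_metrics_in_unit_interval(self, rng):
        adj = (rng.random((10, 10)) < 0.25).astype(int)
        np.fill_diagonal(adj, 0)
        rep = nodal_metrics(_bc(adj))
        for m in ("clustering", "efficiency", "local_efficiency", "betweenness"):
            assert ((rep.nodal[m] >= 0) & (rep.nodal[m] <= 1)).all()

    def test_group_shares_sum_to_one(self, rng):
        adj = (rng.random((8, 8)) < 0.4).astype(int)
        np.fill_diagonal(adj, 0)
        nodes = [f"n{i}" for i in range(8)]
        groups = {n: ("left" if i < 4 else "right") for i, n in enumerate(nodes)}
        rep = nodal_metrics(_bc(adj, nodes), groups=groups)
        assert sum(rep.group_shares.values()) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        adj = (rng.random((n, n)) < 0.45).astype(int)
        np.fill_diagonal(adj, 0)
        rep = nodal_metrics(_bc(adj))
        oracle = brute_nodal_metrics(adj)
        for m in NODAL_METRICS:
            np.testing.assert_allclose(
                rep.nodal[m].to_numpy(), oracle[m], atol=1e-10, err_msg=m
            )


class TestHubs:
    def test_regular_graph_has_no_hubs(self):
        adj = [[0, 1, 0], [0, 0, 1], [1, 0, 0]]  # all DC equal, SD = 0, strict >
        rep = nodal_metrics(_bc(adj))
        assert rep.hub_set == set()

    def test_star_center_is_sole_hub(self):
        rep = nodal_metrics(_star())
        assert detect_hubs(rep.nodal["degree_centrality"]) == {"center"}

    def test_adding_edge_elsewhere_keeps_hub_advantage(self):
        # brute probe over 5-node graphs: a hub's DC never drops when an edge
        # is added between two other nodes
        rng = np.random.default_rng(5)
        for _ in range(50):
            adj = (rng.random((5, 5)) < 0.3).astype(int)
            np.fill_diagonal(adj, 0)
            rep = nodal_metrics(_bc(adj))
            zeros = np.argwhere((adj == 0) & ~np.eye(5, dtype=bool))
            if not len(zeros) or not rep.hub_set:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            adj2 = adj.copy()
            adj2[i, j] = 1
            rep2 = nodal_metrics(_bc(adj2))
            for hub in rep.hub_set:
                k = int(hub[1:])
                if k not in (i, j):
                    assert (
                        rep2.nodal.loc[hub, "degree_centrality"]
                        == rep.nodal.loc[hub, "degree_centrality"]
                    )


class TestErNull:
    def test_saturated_draw_is_complete(self):
        bc = er_null(5, 20, seed=1)
        assert bc.edge_count() == 20
        assert (bc.adjacency + np.eye(5, dtype=int) == 1).all()

    def test_empty_draw(self):
        assert er_null(57, 0, seed=1).edge_count() == 0

    def test_same_seed_reproduces(self):
        a = er_null(20, 57, seed=99)
        b = er_null(20, 57, seed=99)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_edge_count_exact_over_draws(self):
        for seed in range(50):
            bc = er_null(15, 40, seed=seed)
            assert bc.edge_count() == 40
            assert np.trace(bc.adjacency) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            er_null(5, 21, seed=0)


class TestSmallWorld:
    def test_ring_lattice_is_not_small_world(self):
        # directed ring lattice, each node → next 2 both ways: high clustering
        # but long paths versus ER
        n = 30
        adj = np.zeros((n, n), dtype=int)
        for i in range(n):
            for d in (1, 2):
                adj[i, (i + d) % n] = 1
                adj[i, (i - d) % n] = 1
        verdict = small_world_verdict(_bc(adj), n_null=20, seed=3)
        assert verdict.clustering_graph > verdict.clustering_er
        assert verdict.path_graph > verdict.path_er
        assert not verdict.is_small_world

    def test_er_input_not_small_world_in_expectation(self):
        bc = er_null(30, 120, seed=11)
        verdict = small_world_verdict(bc, n_null=30, seed=12)
        assert not verdict.is_small_world


class TestPermutation:
    def test_empty_removal_gives_p_one(self, rng):
        adj = (rng.random((8, 8)) < 0.35).astype(int)
        np.fill_diagonal(adj, 0)
        res = ablation_permutation_test(_bc(adj), set(), "degree_centrality", 200, seed=1)
        assert res.observed_statistic == 0.0
        assert res.p_value == 1.0

    def test_same_seed_is_deterministic(self, rng):
        adj = (rng.random((10, 10)) < 0.3).astype(int)
        np.fill_diagonal(adj, 0)
        bc = _bc(adj)
        r1 = ablation_permutation_test(bc, {"n0", "n1"}, "efficiency", 500, seed=42)
        r2 = ablation_permutation_test(bc, {"n0", "n1"}, "efficiency", 500, seed=42)
        assert r1.p_value == r2.p_value

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1.0, 2.0, 7.0], [3.0, 4.0, 5.0, 6.0]),
            ([0.0, 0.5], [1.5, 2.0, 2.5, 3.0]),
            ([10.0, 11.0, 12.0, 13.0], [9.0, 14.0, 8.0, 15.0]),
        ],
    )
    def test_matches_exhaustive_enumeration(self, a, b):
        exact = exhaustive_permutation_pvalue(a, b)
        _, p = permutation_pvalue(np.array(a), np.array(b), n_perm=40_000, seed=0)
        assert p == pytest.approx(exact, abs=0.01)

    def test_p_at_least_one_over_nperm_plus_one(self, rng):
        a = rng.normal(10, 1, size=20)
        b = rng.normal(0, 1, size=15)
        _, p = permutation_pvalue(a, b, n_perm=999, seed=5)
        assert p == pytest.approx(1 / 1000)

    def test_removing_all_nodes_rejected(self, rng):
        adj = (rng.random((4, 4)) < 0.5).astype(int)
        np.fill_diagonal(adj, 0)
        with pytest.raises(DegenerateInputError):
            ablation_permutation_test(_bc(adj), {"n0", "n1", "n2", "n3"}, "clustering", 10, 0)

    def test_unknown_metric_rejected(self, rng):
        adj = np.zeros((3, 3), dtype=int)
        with pytest.raises(ValueError):
            ablation_permutation_test(_bc(adj), set(), "pagerank", 10, 0)
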