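"""Efficiency measures: closed forms, identities, oracle agreement, monotonicity."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thicknet as tn
from thicknet.efficiency import (
    distance_matrix,
    global_efficiency_array,
    local_efficiency_array,
    neighboring_efficiency_vector,
    nodal_efficiency_vector,
)
from thicknet.errors import SpecError

from conftest import (
    oracle_distances,
    oracle_global_efficiency,
    oracle_local_efficiency,
    random_adjacency,
)


class TestShortestPaths:
    def test_path_graph_distance(self):
        d = tn.shortest_path_lengths(tn.fixture_graph("path", 3))
        assert d[0, 2] == 2

    def test_disconnected_pairs_are_infinite(self):
        d = tn.shortest_path_lengths(tn.fixture_graph("disconnected_pair", 6))
        assert np.isinf(d[0, 5])
        assert d[0, 1] == 1

    def test_matches_floyd_warshall_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            adj = random_adjacency(rng, 10, 0.3)
            assert np.array_equal(distance_matrix(adj), oracle_distances(adj))

    def test_small_and_large_kernels_agree(self):
        """The matrix-power BFS and the csgraph path give identical distances."""
        from scipy.sparse.csgraph import shortest_path
        rng = np.random.default_rng(4)
        for n, p in [(30, 0.1), (64, 0.05), (80, 0.2)]:
            adj = random_adjacency(rng, n, p)
            ref = shortest_path(adj.astype(np.int8), method="D",
                                unweighted=True, directed=False)
            assert np.array_equal(distance_matrix(adj), ref)


class TestClosedForms:
    def test_complete_graph_has_unit_global_efficiency(self):
        assert tn.global_efficiency(tn.fixture_graph("complete", 6)) == 1.0

    def test_empty_graph_has_zero_global_efficiency(self):
        assert tn.global_efficiency(tn.fixture_graph("empty", 6)) == 0.0

    def test_three_node_path_global_efficiency(self):
        assert tn.global_efficiency(tn.fixture_graph("path", 3)) == pytest.approx(5 / 6)

    def test_star_hub_and_leaf_nodal_efficiency(self):
        star = tn.fixture_graph("star", 4)
        assert tn.nodal_efficiency(star, 0) == 1.0
        assert tn.nodal_efficiency(star, 1) == pytest.approx(2 / 3)

    def test_isolated_node_efficiencies_are_zero(self):
        empty = tn.fixture_graph("empty", 4)
        assert tn.nodal_efficiency(empty, 0) == 0.0
        assert tn.neighboring_efficiency(empty, 0) == 0.0

    def test_degree_one_node_neighboring_efficiency_zero(self):
        path = tn.fixture_graph("path", 3)
        assert tn.neighboring_efficiency(path, 0) == 0.0

    def test_path_center_neighboring_efficiency_is_whole_path(self):
        """Node 1's subgraph (itself + both neighbors) is the whole 3-path."""
        path = tn.fixture_graph("path", 3)
        assert tn.neighboring_efficiency(path, 1) == pytest.approx(5 / 6)

    def test_triangle_node_neighboring_efficiency_one(self):
        tri = tn.fixture_graph("complete", 3)
        assert tn.neighboring_efficiency(tri, 0) == 1.0

    def test_local_efficiency_extremes(self):
        assert tn.local_efficiency(tn.fixture_graph("complete", 5)) == 1.0
        assert tn.local_efficiency(tn.fixture_graph("empty", 5)) == 0.0

    def test_neighbors_only_convention_differs_on_path(self):
        """Center of a 3-path: neighbors-only subgraph is two unlinked nodes."""
        path = tn.fixture_graph("path", 3)
        assert tn.neighboring_efficiency(path, 1, convention="neighbors_only") == 0.0


class TestIdentitiesAndOracle:
    def test_identities_and_oracle_on_random_graphs(self):
        """All four measures match the brute-force oracle; identities hold."""
        rng = np.random.default_rng(1)
        for _ in range(60):
            n = rng.integers(2, 8)
            adj = random_adjacency(rng, n, rng.uniform(0.1, 0.9))
            e_nodal = nodal_efficiency_vector(adj)
            e_nbr = neighboring_efficiency_vector(adj)
            e_glob = global_efficiency_array(adj)
            e_loc = local_efficiency_array(adj)
            assert e_glob == pytest.approx(oracle_global_efficiency(adj), abs=1e-12)
            assert e_loc == pytest.approx(oracle_local_efficiency(adj), abs=1e-12)
            assert e_glob == pytest.approx(e_nodal.mean(), abs=1e-12)
            assert e_loc == pytest.approx(e_nbr.mean(), abs=1e-12)
            assert ((0 <= e_nodal) & (e_nodal <= 1)).all()
            assert ((0 <= e_nbr) & (e_nbr <= 1)).all()

    def test_global_efficiency_matches_networkx(self):
        """Independent library cross-check on larger graphs."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            adj = random_adjacency(rng, 40, 0.1)
            g = nx.from_numpy_array(adj)
            assert global_efficiency_array(adj) == pytest.approx(
                nx.global_efficiency(g), abs=1e-12
            )

    def test_neighbors_only_convention_matches_networkx_local_efficiency(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            adj = random_adjacency(rng, 25, 0.2)
            g = nx.from_numpy_array(adj)
            assert local_efficiency_array(adj, "neighbors_only") == pytest.approx(
                nx.local_efficiency(g), abs=1e-12
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_adding_an_edge_never_decreases_global_or_nodal_efficiency(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        adj = random_adjacency(rng, n, 0.3)
        absent = [(i, j) for i in range(n) for j in range(i + 1, n) if not adj[i, j]]
        if not absent:
            return
        i, j = absent[rng.integers(len(absent))]
        before_nodal = nodal_efficiency_vector(adj)
        adj2 = adj.copy()
        adj2[i, j] = adj2[j, i] = 1
        after_nodal = nodal_efficiency_vector(adj2)
        assert (after_nodal >= before_nodal - 1e-12).all()
        assert global_efficiency_array(adj2) >= global_efficiency_array(adj) - 1e-12


class TestCostAveraged:
    def test_constant_series(self, small_grid):
        assert tn.cost_averaged([0.3] * len(small_grid), small_grid) == pytest.approx(0.3)

    def test_two_point_mean(self):
        grid = tn.CostGrid((0.1, 0.2))
        assert tn.cost_averaged([0.0, 1.0], grid) == 0.5

    def test_linear_ramp_gives_midpoint(self):
        grid = tn.CostGrid.from_range(0.01, 0.50, 0.01)
        ramp = np.linspace(0.0, 1.0, 50)
        assert tn.cost_averaged(ramp, grid) == pytest.approx(0.5)

    def test_length_mismatch_rejected(self, small_grid):
        with pytest.raises(SpecError):
            tn.cost_averaged([1.0], small_grid)


class TestSmallWorldAssessment:
    def test_random_instance_sits_inside_random_ensemble(self):
        grid = tn.CostGrid((0.2,))
        brain = [tn.random_network(30, 87, seed=0)]
        sw = tn.small_world_assessment(brain, grid, n_null=50, seed=1)
        # a random draw's E_glob lies within the null ensemble's spread
        ensemble = [
            tn.global_efficiency(tn.random_network(30, 87, seed=s)) for s in range(50)
        ]
        assert min(ensemble) <= sw.e_glob_brain[0] <= max(ensemble)
        assert abs(sw.e_glob_brain[0] - sw.e_glob_random[0]) < 0.05

    def test_lattice_input_boundary_holds_with_tolerance(self):
        grid = tn.CostGrid((0.15,))
        k = int(round(0.15 * 30 * 29 / 2))
        brain = [tn.lattice_network(30, k)]
        sw = tn.small_world_assessment(brain, grid, n_null=20, seed=2)
        assert sw.e_loc_brain[0] == pytest.approx(sw.e_loc_lattice[0], abs=1e-12)
        assert sw.loc_sandwich[0]

    def test_random_beats_lattice_globally_at_matched_cost(self):
        grid = tn.CostGrid((0.15,))
        brain = [tn.random_network(40, 117, seed=3)]
        sw = tn.small_world_assessment(brain, grid, n_null=30, seed=4)
        assert sw.e_glob_random[0] > sw.e_glob_lattice[0]
        assert sw.e_loc_lattice[0] > sw.e_loc_random[0]

    def test_invalid_n_null_rejected(self):
        grid = tn.CostGrid((0.2,))
        with pytest.raises(SpecError):
            tn.small_world_assessment([tn.random_network(10, 9, seed=0)], grid, n_null=0)
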