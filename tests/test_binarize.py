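import numpy as np
import pytest

from acunet import (
    binarize,
    edge_density,
    is_fully_connected,
    scan_thresholds,
    select_by_density,
)
from acunet.binarize import BinarizeError, nearest_to_density
from acunet.mi import MIMatrix

from conftest import adjacency_from_edges, random_adjacency
from oracles import reachable_by_powering


def mi_from_upper(n, entries):
    vals = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals[iu] = entries
    vals = vals + vals.T
    return MIMatrix(labels=tuple(f"N{i}" for i in range(n)), values=vals)


def random_mi(rng, n):
    return mi_from_upper(n, rng.uniform(-0.1, 0.6, size=n * (n - 1) // 2))


class TestBinarize:
    def test_threshold_below_minimum_gives_complete_graph(self):
        mi = random_mi(np.random.default_rng(0), 6)
        adj = binarize(mi, -1.0)
        assert adj.edge_count == 15

    def test_threshold_above_maximum_gives_empty_graph(self):
        mi = random_mi(np.random.default_rng(0), 6)
        assert binarize(mi, 1.0).edge_count == 0

    def test_hand_counted_edges(self):
        mi = mi_from_upper(4, [0.1, 0.2, 0.3, 0.05, 0.25, 0.15])
        assert binarize(mi, 0.18).edge_count == 3

    def test_edge_rule_is_strict(self):
        mi = mi_from_upper(2, [0.5])
        assert binarize(mi, 0.5).edge_count == 0
        assert binarize(mi, 0.499).edge_count == 1


class TestEdgeDensity:
    def test_complete_and_empty(self):
        full = adjacency_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
        empty = adjacency_from_edges(4, [])
        assert edge_density(full) == 1.0
        assert edge_density(empty) == 0.0

    def test_direct_arithmetic_at_p33(self):
        # 211 edges out of 33*32/2 = 528 pairs
        rng = np.random.default_rng(1)
        pairs = [(i, j) for i in range(33) for j in range(i + 1, 33)]
        idx = rng.choice(len(pairs), size=211, replace=False)
        adj = adjacency_from_edges(33, [pairs[i] for i in idx])
        assert edge_density(adj) == pytest.approx(211 / 528)

    def test_single_node_errors(self):
        with pytest.raises(BinarizeError):
            edge_density(adjacency_from_edges(1, []))


class TestConnectivity:
    def test_path_graph_connected(self):
        adj = adjacency_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        assert is_fully_connected(adj)

    def test_two_triangles_disconnected(self):
        adj = adjacency_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert not is_fully_connected(adj)

    def test_agrees_with_matrix_powering_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            adj = random_adjacency(rng, int(rng.integers(2, 9)), float(rng.uniform(0.1, 0.7)))
            assert is_fully_connected(adj) == reachable_by_powering(adj.edges)


class TestThresholdScan:
    def test_uniform_matrix_r_max(self):
        mi = mi_from_upper(4, [0.5] * 6)
        scan = scan_thresholds(mi)
        assert scan.r_max_connected == 0.499  # strict > drops all edges at 0.500

    def test_isolated_node_flagged(self):
        # one node with no positive association to anything
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 0.4
        mi = MIMatrix(labels=("A", "B", "C"), values=vals)
        scan = scan_thresholds(mi)
        assert scan.r_max_connected is None
        assert not any(scan.connected)

    def test_two_block_matrix_disconnects_above_interblock_mi(self):
        # strong blocks {0,1} and {2,3}, weak bridge eps = 0.010
        eps = 0.010
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = 0.5
        vals[2, 3] = vals[3, 2] = 0.5
        vals[1, 2] = vals[2, 1] = eps
        mi = MIMatrix(labels=("A", "B", "C", "D"), values=vals)
        scan = scan_thresholds(mi)
        assert scan.r_max_connected is not None
        assert scan.r_max_connected < eps

    def test_edge_count_non_increasing_and_nested(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            mi = random_mi(rng, 8)
            scan = scan_thresholds(mi, grid=range(1, 1000, 37))
            assert all(
                b <= a for a, b in zip(scan.edge_counts, scan.edge_counts[1:])
            )
            prev = None
            for r in scan.grid:
                edges = binarize(mi, r).edge_set()
                if prev is not None:
                    assert edges <= prev
                prev = edges

    def test_empty_grid_rejected(self):
        mi = mi_from_upper(3, [0.1, 0.2, 0.3])
        with pytest.raises(BinarizeError):
            scan_thresholds(mi, grid=[])

    def test_connectivity_monotone_in_r(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            mi = random_mi(rng, 7)
            scan = scan_thresholds(mi)
            conn = list(scan.connected)
            # once disconnected, stays disconnected as R grows
            seen_false = False
            for c in conn:
                if not c:
                    seen_false = True
                assert not (seen_false and c)


class TestSelectByDensity:
    def test_full_band_returns_every_connected_network(self):
        rng = np.random.default_rng(5)
        mi = random_mi(rng, 6)
        nets = select_by_density(mi, 1e-9, 1.0)
        scan = scan_thresholds(mi)
        distinct_connected = {
            cnt
            for cnt, conn in zip(scan.edge_counts, scan.connected)
            if conn and cnt > 0
        }
        assert {n.edge_count for n in nets} == distinct_connected

    def test_sparsest_admissible_first(self):
        mi = random_mi(np.random.default_rng(6), 8)
        nets = select_by_density(mi, 0.2, 1.0)
        dens = [edge_density(n) for n in nets]
        assert dens == sorted(dens)

    def test_empty_selection_suggests_wider_band(self):
        mi = mi_from_upper(3, [0.5, 0.5, 0.5])
        with pytest.raises(BinarizeError, match="widen"):
            select_by_density(mi, 0.001, 0.002)

    def test_invalid_band_rejected(self):
        mi = mi_from_upper(3, [0.5, 0.5, 0.5])
        with pytest.raises(BinarizeError):
            select_by_density(mi, 0.7, 0.2)

    def test_lbp_band_is_reachable(self, lbp_mi):
        nets = select_by_density(lbp_mi, 0.39, 0.50)
        assert nets
        assert all(is_fully_connected(n) for n in nets)
        assert all(0.39 <= edge_density(n) <= 0.50 for n in nets)

    def test_nearest_to_density_prefers_larger_r_on_ties(self):
        mi = random_mi(np.random.default_rng(7), 8)
        nets = select_by_density(mi, 1e-9, 1.0)
        best = nearest_to_density(nets, 0.4)
        gap = abs(edge_density(best) - 0.4)
        ties = [n for n in nets if abs(edge_density(n) - 0.4) == gap]
        assert best.threshold == max(t.threshold for t in ties)
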