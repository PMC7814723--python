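import numpy as np
import pytest

import healthreach as hr
from healthreach.hotspots import (
    gi_star,
    multi_order_clusters,
    permutation_p,
    queen_weights,
    queen_weights_from_labels,
    zonal_mean,
)

from oracles import gi_star_reference


def lattice_labels(n, zone_rows=1, zone_cols=1):
    """n x n lattice of zones, each zone a block of cells."""
    lab = np.arange(n * n).reshape(n, n)
    return np.kron(lab, np.ones((zone_rows, zone_cols), dtype=int))


def path_graph_weights(n):
    lab = np.arange(n).reshape(1, n)
    return queen_weights_from_labels(np.vstack([lab, lab]))


class TestQueenWeights:
    def test_center_zone_has_eight_neighbors(self):
        w = queen_weights(lattice_labels(3, 2, 2))
        assert w.adjacency[1][4].sum() == 8

    def test_corner_zone_order_two_reaches_all(self):
        w = queen_weights(lattice_labels(3, 2, 2))
        assert w.adjacency[2][0].sum() == 8

    def test_orders_are_cumulative(self):
        w = queen_weights(lattice_labels(5, 2, 2))
        for i in range(w.n):
            assert set(np.nonzero(w.adjacency[1][i])[0]) <= set(
                np.nonzero(w.adjacency[2][i])[0]
            )
            assert set(np.nonzero(w.adjacency[2][i])[0]) <= set(
                np.nonzero(w.adjacency[3][i])[0]
            )

    def test_symmetry(self):
        w = queen_weights(lattice_labels(4, 3, 3))
        for k in (1, 2, 3):
            assert np.array_equal(w.adjacency[k], w.adjacency[k].T)

    def test_isolated_zone_warns_and_excluded(self):
        # zone 2 is separated from the rest by a masked (-1) moat
        lab = np.full((7, 7), -1)
        lab[:3, :3] = 0
        lab[:3, 3] = 1
        lab[5:, 5:] = 2  # zone 2 is cut off by the moat
        with pytest.warns(UserWarning, match="no order-1 neighbor"):
            w = queen_weights_from_labels(lab)
        assert not w.active[2] and w.active[0] and w.active[1]

    def test_polygon_path_counts_corner_contact(self):
        # a 3x3 lattice of square polygons: the center touches all 8,
        # corners touch 3 (edge) + no, queen counts the diagonal too
        from shapely.geometry import box as shp_box

        from healthreach.hotspots import queen_weights_from_polygons

        polys = [shp_box(c, r, c + 1, r + 1) for r in range(3) for c in range(3)]
        w = queen_weights_from_polygons(polys)
        assert w.adjacency[1][4].sum() == 8
        assert w.adjacency[1][0].sum() == 3
        assert w.adjacency[1][0][4]  # corner-only contact counts (queen)

    def test_polygon_and_label_paths_mostly_agree(self, small_scene):
        # the raster path can add/miss hairline contacts near shared corners;
        # the two adjacency graphs must still agree on almost every pair
        from healthreach.hotspots import queen_weights_from_polygons

        wl = queen_weights_from_labels(small_scene.parishes.labels, max_order=1)
        wp = queen_weights_from_polygons(small_scene.parishes.polygons, max_order=1)
        diff = np.logical_xor(wl.adjacency[1], wp.adjacency[1]).sum()
        both = (wl.adjacency[1] | wp.adjacency[1]).sum()
        assert diff / both < 0.15


class TestGiStar:
    def test_constant_values_rejected(self):
        w = path_graph_weights(5)
        with pytest.raises(ValueError, match="variance"):
            gi_star(np.ones(5), w)

    def test_hand_computed_path_graph(self):
        # 4 zones in a row, values (10,0,0,0): for zone 0, W=2, lag=10,
        # mean=2.5, s=sqrt(18.75) -> z = (10-5)/(s*sqrt((8-4)/3)) = 1.0
        w = path_graph_weights(4)
        z = gi_star(np.array([10.0, 0.0, 0.0, 0.0]), w)
        assert z[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_reference_loop_implementation(self, seed):
        rng = np.random.default_rng(seed)
        side = rng.integers(4, 7)
        w = queen_weights(lattice_labels(side))
        x = rng.normal(size=side * side)
        for order in (1, 2, 3):
            mine = gi_star(x, w, order=order)
            ref = gi_star_reference(x, w.neighbors(order))
            np.testing.assert_allclose(mine, ref, rtol=0, atol=1e-9)


class TestPermutationP:
    def test_deterministic_given_seed(self):
        w = queen_weights(lattice_labels(5))
        x = np.random.default_rng(0).normal(size=25)
        p1 = permutation_p(x, w, order=1, n_perm=999, seed=42)
        p2 = permutation_p(x, w, order=1, n_perm=999, seed=42)
        np.testing.assert_array_equal(p1, p2)

    def test_minimum_permutations_enforced(self):
        w = queen_weights(lattice_labels(4))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_p(np.arange(16.0), w, n_perm=99)

    def test_null_p_values_roughly_uniform(self):
        # fraction of p <= 0.05 should sit near 0.05 under no spatial structure
        rng = np.random.default_rng(7)
        w = queen_weights(lattice_labels(6))
        hits, total = 0, 0
        for _ in range(30):
            x = rng.normal(size=36)
            p = permutation_p(x, w, order=1, n_perm=999, seed=int(rng.integers(2**31)))
            hits += int((p <= 0.05).sum())
            total += len(p)
        assert 0.03 <= hits / total <= 0.07

    def test_planted_block_reaches_extreme_significance(self):
        w = queen_weights(lattice_labels(7))
        x = np.zeros(49)
        block = [16, 17, 23, 24, 25]  # contiguous 5-zone high block
        x[block] = 10.0
        x += np.random.default_rng(1).normal(scale=0.1, size=49)
        p = permutation_p(x, w, order=1, n_perm=9999, seed=5)
        assert np.all(p[[17, 24]] <= 0.001)


class TestMultiOrderRule:
    def test_label_requires_significance_at_same_order(self):
        rng = np.random.default_rng(3)
        w = queen_weights(lattice_labels(6))
        x = rng.normal(size=36)
        res = multi_order_clusters(x, w, alpha=0.001, n_perm=999, seed=0)
        for oi in range(len(res.orders)):
            labeled = res.label[oi] != "none"
            assert np.all(res.p[oi][labeled] <= res.alpha)

    def test_no_significant_zone_all_none(self):
        w = queen_weights(lattice_labels(4))
        x = np.random.default_rng(11).normal(size=16)
        res = multi_order_clusters(x, w, alpha=1e-4, n_perm=999, seed=0)
        # with n_perm=999 the smallest attainable p is 1e-3 > alpha
        assert np.all(res.cluster == "none") and np.all(res.order == 0)

    def test_decreasing_magnitude_stops_at_order_one(self):
        # a compact 2x2 high block: for its zones |z| is largest at order 1
        # and decays as the window grows past the block, so the monotone rule
        # can only ever label them at order 1
        w = queen_weights(lattice_labels(9))
        x = np.zeros(81)
        block = [30, 31, 39, 40]
        x[block] = 10.0
        x += np.random.default_rng(2).normal(scale=0.2, size=81)
        res = multi_order_clusters(x, w, alpha=0.01, n_perm=9999, seed=1)
        for b in block:
            assert res.order[b] == 1 and res.cluster[b] == "high"
            assert abs(res.z[0, b]) > abs(res.z[1, b]) > abs(res.z[2, b])


class TestZonalMean:
    def test_constant_raster_gives_constant(self):
        labels = lattice_labels(2, 3, 3)
        out = zonal_mean(np.full((6, 6), 42.0), labels)
        np.testing.assert_allclose(out, 42.0)

    def test_two_zone_hand_arithmetic(self):
        minutes = np.array([[10.0, 20.0], [30.0, 40.0]])
        labels = np.array([[0, 0], [1, 1]])
        np.testing.assert_allclose(zonal_mean(minutes, labels), [15.0, 35.0])

    def test_unreachable_zone_missing_with_warning(self):
        minutes = np.array([[np.inf, np.inf], [5.0, 7.0]])
        labels = np.array([[0, 0], [1, 1]])
        with pytest.warns(UserWarning, match="no finite"):
            out = zonal_mean(minutes, labels)
        assert np.isnan(out[0]) and out[1] == pytest.approx(6.0)
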