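import numpy as np
import pytest
from shapely.geometry import Polygon

from thermoseal import (
    BinaryGrid,
    PixelCluster,
    convex_hull_ratio,
    extract_clusters,
    polygonize_cluster,
    select_hot_pixels,
)


def brute_force_select(values, nodata, t_min):
    """Cell-by-cell loop oracle for thresholding."""
    out = np.zeros(values.shape, dtype=bool)
    for r in range(values.shape[0]):
        for c in range(values.shape[1]):
            v = values[r, c]
            out[r, c] = (v != nodata) and not np.isnan(v) and v >= t_min
    return out


def flood_fill_clusters(selected, connectivity):
    """Independent flood-fill oracle for connected components."""
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros(selected.shape, dtype=bool)
    comps = []
    for r in range(selected.shape[0]):
        for c in range(selected.shape[1]):
            if selected[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < selected.shape[0] and 0 <= nc < selected.shape[1]
                                and selected[nr, nc] and not seen[nr, nc]):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(frozenset(comp))
    return set(comps)


class TestSelectHotPixels:
    def test_threshold_is_inclusive_and_skips_nodata(self, make_raster):
        r = make_raster([[8.9, 9.0], [10.2, -9999.0]])
        sel = select_hot_pixels(r, 9.0)
        assert set(zip(*np.nonzero(sel.selected))) == {(0, 1), (1, 0)}

    def test_all_below_threshold_selects_nothing(self, make_raster):
        r = make_raster(np.full((4, 4), 3.0))
        assert select_hot_pixels(r, 9.0).count == 0

    def test_matches_brute_force_on_random_grids(self, make_raster):
        rng = np.random.default_rng(3)
        for _ in range(10):
            vals = rng.normal(9, 2, (50, 50))
            vals[rng.random((50, 50)) < 0.05] = -9999.0
            r = make_raster(vals)
            sel = select_hot_pixels(r, 9.0)
            assert np.array_equal(sel.selected, brute_force_select(vals, -9999.0, 9.0))

    def test_raising_threshold_never_adds_cells(self, make_raster):
        rng = np.random.default_rng(4)
        r = make_raster(rng.normal(9, 3, (30, 30)))
        counts = [select_hot_pixels(r, t).count for t in np.linspace(4, 14, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_nonfinite_threshold_rejected(self, make_raster):
        r = make_raster(np.ones((2, 2)))
        with pytest.raises(ValueError):
            select_hot_pixels(r, float("nan"))


class TestExtractClusters:
    def test_diagonal_pair_depends_on_connectivity(self):
        grid = np.zeros((3, 3), dtype=bool)
        grid[0, 0] = grid[1, 1] = True
        assert len(extract_clusters(BinaryGrid(grid), 4)) == 2
        assert len(extract_clusters(BinaryGrid(grid), 8)) == 1

    def test_empty_grid_gives_no_clusters(self):
        assert extract_clusters(BinaryGrid(np.zeros((5, 5), dtype=bool))) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_grids(self, connectivity):
        rng = np.random.default_rng(5)
        for _ in range(10):
            grid = rng.random((40, 40)) < 0.35
            clusters = extract_clusters(BinaryGrid(grid), connectivity)
            got = {cl.cells for cl in clusters}
            assert got == flood_fill_clusters(grid, connectivity)
            # conservation: clusters partition the selected cells
            assert sum(len(cl) for cl in clusters) == grid.sum()

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            extract_clusters(BinaryGrid(np.ones((2, 2), dtype=bool)), 6)


def shoelace(coords):
    xs, ys = zip(*coords)
    n = len(coords)
    return abs(sum(xs[i] * ys[(i + 1) % n] - xs[(i + 1) % n] * ys[i]
                   for i in range(n))) / 2


class TestPolygonize:
    def test_single_pixel_area_is_gsd_squared(self, make_raster):
        r = make_raster(np.full((3, 3), 12.0))
        cl = PixelCluster(np.array([1]), np.array([1]))
        poly = polygonize_cluster(cl, r)
        assert poly.area_m2 == pytest.approx(0.0064)
        assert poly.pixel_count == 1
        assert poly.chull_ratio == pytest.approx(1.0)

    def test_mean_temperature_of_block(self, make_raster):
        vals = np.zeros((4, 4))
        vals[1, 1], vals[1, 2], vals[2, 1], vals[2, 2] = 10.0, 12.0, 11.0, 11.0
        r = make_raster(vals)
        cl = PixelCluster(np.array([1, 1, 2, 2]), np.array([1, 2, 1, 2]))
        assert polygonize_cluster(cl, r).mean_temp_c == pytest.approx(11.0)

    def test_l_shape_geometric_area_matches_pixel_count(self, make_raster):
        r = make_raster(np.full((4, 4), 12.0))
        cl = PixelCluster(np.array([0, 1, 1]), np.array([0, 0, 1]))
        poly = polygonize_cluster(cl, r)
        assert poly.area_m2 == pytest.approx(3 * 0.08 ** 2)
        # shoelace oracle on the polygon's own exterior ring
        ring = list(poly.geometry.exterior.coords)[:-1]
        assert shoelace(ring) == pytest.approx(3 * 0.08 ** 2)
        assert poly.geometry.area == pytest.approx(poly.area_m2)


class TestConvexHullRatio:
    def test_convex_square_is_one(self):
        sq = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert convex_hull_ratio(sq) == pytest.approx(1.0)

    def test_l_shape_matches_hand_computation(self):
        l_shape = Polygon([(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)])
        # area 3; hull (0,0),(2,0),(2,1),(1,2),(0,2) has shoelace area 3.5
        assert convex_hull_ratio(l_shape) == pytest.approx(3 / 3.5)

    def test_zero_area_rejected(self):
        degenerate = Polygon([(0, 0), (1, 0), (0, 0)])
        with pytest.raises(ValueError):
            convex_hull_ratio(degenerate)

    def test_never_exceeds_one_on_random_rasterized_clusters(self, make_raster):
        rng = np.random.default_rng(6)
        r = make_raster(np.full((20, 20), 12.0))
        grid = rng.random((20, 20)) < 0.4
        for cl in extract_clusters(BinaryGrid(grid)):
            assert polygonize_cluster(cl, r).chull_ratio <= 1.0 + 1e-12
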