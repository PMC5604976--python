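"""Grid geometry, rasterization and the distance transform."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hpvsdm import (GridSpec, OutOfDomainError, RasterLayer, cell_of,
                    distance_to_nearest, haversine_m, rasterize_count,
                    read_ascii_grid, to_presence, write_ascii_grid,
                    read_points_csv, write_points_csv, points_to_geojson,
                    geojson_to_points, EARTH_RADIUS_M)
from conftest import random_points


class TestCellOf:
    def test_northwest_corner_is_cell_0_0(self, small_grid):
        res = small_grid.resolution
        assert cell_of(small_grid.xmin, small_grid.ymax - 1e-9,
                       small_grid) == (0, 0)

    def test_floor_convention(self, small_grid):
        res = small_grid.resolution
        lon = small_grid.xmin + 1.5 * res
        lat = small_grid.ymax - 2.5 * res
        assert cell_of(lon, lat, small_grid) == (2, 1)

    def test_outside_point_raises_naming_the_point(self, small_grid):
        with pytest.raises(OutOfDomainError, match="lon=30"):
            cell_of(30.0, 52.05, small_grid)

    def test_matches_loop_based_assignment(self, small_grid, rng):
        pts = random_points(rng, small_grid, 1000)
        res = small_grid.resolution
        for lon, lat in pts:
            # independent loop oracle: scan cells until the point fits
            row = col = None
            for r in range(small_grid.nrows):
                top = small_grid.ymax - r * res
                if top - res < lat <= top:
                    row = r
                    break
            for c in range(small_grid.ncols):
                left = small_grid.xmin + c * res
                if left <= lon < left + res:
                    col = c
                    break
            assert cell_of(lon, lat, small_grid) == (row, col)


class TestRasterizeCount:
    def test_counts_multiple_points_per_cell(self, small_grid):
        c00 = small_grid.cell_center(0, 0)
        c55 = small_grid.cell_center(5, 5)
        pts = np.array([c00, c00, c00, c55])
        layer = rasterize_count(pts, small_grid)
        assert layer.values[0, 0] == 3
        assert layer.values[5, 5] == 1
        assert layer.values.sum() == 4

    def test_empty_point_list_gives_zero_layer(self, small_grid):
        layer = rasterize_count(np.empty((0, 2)), small_grid)
        assert layer.values.sum() == 0

    def test_matches_brute_force_tally(self, small_grid, rng):
        pts = random_points(rng, small_grid, 200)
        layer = rasterize_count(pts, small_grid)
        brute = np.zeros(small_grid.shape, dtype=int)
        for lon, lat in pts:
            r, c = cell_of(lon, lat, small_grid)
            brute[r, c] += 1
        np.testing.assert_array_equal(layer.values, brute)

    def test_conserves_point_count_property(self, small_grid, rng):
        for n in (1, 17, 230):
            pts = random_points(rng, small_grid, n)
            assert rasterize_count(pts, small_grid).values.sum() == n


class TestToPresence:
    def test_thresholds_counts(self, small_grid):
        vals = np.zeros(small_grid.shape, dtype=np.int32)
        vals[0, :3] = [0, 1, 5]
        layer = RasterLayer(small_grid, "c", vals, nodata=-1)
        pres = to_presence(layer)
        assert list(pres.values[0, :3]) == [0, 1, 1]

    def test_idempotent(self, small_grid, rng):
        pts = random_points(rng, small_grid, 100)
        count = rasterize_count(pts, small_grid)
        once = to_presence(count)
        twice = to_presence(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_presence_sum_counts_occupied_cells(self, small_grid, rng):
        pts = random_points(rng, small_grid, 150)
        count = rasterize_count(pts, small_grid)
        pres = to_presence(count)
        assert pres.values.sum() == (count.values > 0).sum()

    def test_negative_counts_rejected(self, small_grid):
        vals = np.full(small_grid.shape, -2, dtype=np.int32)
        with pytest.raises(ValueError, match="negative"):
            to_presence(RasterLayer(small_grid, "c", vals, nodata=-1))

    def test_nodata_preserved(self, small_grid):
        vals = np.ones(small_grid.shape, dtype=np.int32)
        vals[3, 3] = -1
        pres = to_presence(RasterLayer(small_grid, "c", vals, nodata=-1))
        assert pres.values[3, 3] == -1
        assert pres.values[0, 0] == 1


class TestDistanceToNearest:
    def test_zero_at_a_point_on_a_cell_center(self, small_grid):
        lon, lat = small_grid.cell_center(4, 7)
        layer = distance_to_nearest(np.array([[lon, lat]]), small_grid)
        assert layer.values[4, 7] < 1e-6

    def test_neighbour_cell_matches_closed_form_haversine(self, small_grid):
        lon, lat = small_grid.cell_center(4, 7)
        layer = distance_to_nearest(np.array([[lon, lat]]), small_grid)
        expected = haversine_m(lon, lat, lon + small_grid.resolution, lat)
        assert layer.values[4, 8] == pytest.approx(float(expected), abs=1e-6)

    def test_matches_all_pairs_brute_force(self, small_grid, rng):
        pts = random_points(rng, small_grid, 10)
        layer = distance_to_nearest(pts, small_grid)
        for r in range(small_grid.nrows):
            for c in range(small_grid.ncols):
                lon, lat = small_grid.cell_center(r, c)
                best = min(haversine_m(lon, lat, p[0], p[1]) for p in pts)
                assert abs(layer.values[r, c] - best) < 1e-6

    def test_empty_point_set_is_an_error(self, small_grid):
        with pytest.raises(ValueError, match="at least one point"):
            distance_to_nearest(np.empty((0, 2)), small_grid)

    def test_adding_points_never_increases_distance(self, small_grid, rng):
        a = random_points(rng, small_grid, 5)
        b = random_points(rng, small_grid, 3)
        da = distance_to_nearest(a, small_grid).values
        dab = distance_to_nearest(np.vstack([a, b]), small_grid).values
        assert (dab <= da + 1e-9).all()

    def test_union_is_pointwise_minimum(self, small_grid, rng):
        a = random_points(rng, small_grid, 6)
        b = random_points(rng, small_grid, 4)
        da = distance_to_nearest(a, small_grid).values
        db = distance_to_nearest(b, small_grid).values
        dab = distance_to_nearest(np.vstack([a, b]), small_grid).values
        np.testing.assert_allclose(dab, np.minimum(da, db), atol=1e-6)

    def test_occupied_cell_within_half_diagonal(self, small_grid, rng):
        pts = random_points(rng, small_grid, 20)
        layer = distance_to_nearest(pts, small_grid)
        half_diag = haversine_m(
            small_grid.xmin, small_grid.ymax,
            small_grid.xmin + small_grid.resolution,
            small_grid.ymax - small_grid.resolution) / 2.0
        for lon, lat in pts:
            r, c = cell_of(lon, lat, small_grid)
            assert layer.values[r, c] <= half_diag * 1.001


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.integers(1, 60))
def test_count_conservation_property(seed, n):
    grid = GridSpec.from_origin(10.0, 45.0, 12, 9)
    pts = random_points(np.random.default_rng(seed), grid, n)
    assert rasterize_count(pts, grid).values.sum() == n


class TestRasterIO:
    def test_ascii_grid_roundtrip(self, small_grid, rng, tmp_path):
        layer = RasterLayer(small_grid, "field",
                            rng.standard_normal(small_grid.shape))
        path = tmp_path / "field.asc"
        write_ascii_grid(layer, path)
        back = read_ascii_grid(path)
        assert back.grid == small_grid
        np.testing.assert_allclose(back.values, layer.values, rtol=1e-9)

    def test_points_csv_roundtrip(self, tmp_path, rng):
        lons = rng.uniform(19, 20, 5)
        lats = rng.uniform(52, 53, 5)
        onset = np.arange(1980, 1985)
        path = tmp_path / "pts.csv"
        write_points_csv(path, lons, lats, onset_year=onset,
                         census_year=[2007] * 5, ids=[f"s{i}" for i in range(5)])
        back = read_points_csv(path)
        np.testing.assert_allclose(back["lon"], lons)
        np.testing.assert_allclose(back["lat"], lats)
        np.testing.assert_array_equal(back["onset_year"], onset)

    def test_geojson_roundtrip(self, rng):
        lons = rng.uniform(19, 20, 4)
        lats = rng.uniform(52, 53, 4)
        obj = points_to_geojson(lons, lats, [{"id": i} for i in range(4)])
        pts, props = geojson_to_points(obj)
        np.testing.assert_allclose(pts[:, 0], lons)
        np.testing.assert_allclose(pts[:, 1], lats)
        assert props[2]["id"] == 2
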