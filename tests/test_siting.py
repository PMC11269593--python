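"""Weighted-overlay siting score: reclass, distances, exclusions, classes."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from batwind.grids import GridSpec, PointTable
from batwind.siting import (
    DEFAULT_WEIGHTS,
    SITING_HIGH,
    SITING_LOW,
    SITING_MODERATE,
    CriterionSpec,
    build_exclusion_mask,
    classify_siting,
    default_criteria,
    distance_to_features,
    reclassify,
    turbine_score_quantile,
    weighted_overlay,
)

from conftest import make_raster


def _score_rasters(grid, scores):
    return {name: make_raster(grid, np.full(grid.shape, s, dtype=np.int32),
                              nodata=-1, kind="ordinal")
            for name, s in scores.items()}


class TestReclassify:
    def test_band_lookup_conventions(self, grid_3x3):
        spec = CriterionSpec("slope", 2,
                             edges=(-np.inf, 5.0, 10.0, np.inf), scores=(4, 3, 0))
        vals = np.array([[1.0, 5.0, 7.0], [10.0, 12.0, 4.9], [5.0, 9.99, 100.0]])
        out = reclassify(make_raster(grid_3x3, vals), spec)
        np.testing.assert_array_equal(
            out.values, [[4, 3, 3], [0, 0, 4], [3, 3, 0]])

    def test_value_below_first_breakpoint_gets_first_score(self, grid_3x3):
        spec = CriterionSpec("d", 2, edges=(-np.inf, 1000.0, np.inf), scores=(4, 0))
        out = reclassify(make_raster(grid_3x3, np.full((3, 3), -50.0)), spec)
        assert (out.values == 4).all()

    def test_uncovered_value_errors_with_offenders(self, grid_3x3):
        spec = CriterionSpec("wpc", 3, mapping={1: 0, 2: 2, 3: 4})
        raster = make_raster(grid_3x3, np.full((3, 3), 9, dtype=np.int32),
                             nodata=-1, kind="ordinal")
        with pytest.raises(ValueError, match="9"):
            reclassify(raster, spec)

    def test_nodata_propagates(self, grid_3x3):
        spec = CriterionSpec("wpc", 3, mapping={1: 4})
        vals = np.ones((3, 3), dtype=np.int32)
        vals[1, 1] = -1
        out = reclassify(make_raster(grid_3x3, vals, nodata=-1, kind="ordinal"),
                         spec)
        assert out.values[1, 1] == out.nodata

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CriterionSpec("bad", 2, mapping={1: 9})
        with pytest.raises(ValueError):
            CriterionSpec("bad", 0, mapping={1: 1})


class TestDistance:
    def test_pythagorean_point_distance(self):
        grid = GridSpec(0, 10_000, 1000, 10, 10, "local")
        # feature at a cell center; target center 3 km east, 4 km north
        feature = Point(1500.0, 1500.0)
        out = distance_to_features([feature], grid)
        row, col, _ = grid.index_of(np.array([4500.0]), np.array([5500.0]))
        assert out.values[row[0], col[0]] == pytest.approx(5000.0)

    def test_cell_center_on_line_is_zero(self):
        grid = GridSpec(0, 3000, 1000, 3, 3, "local")
        line = LineString([(500, 2500), (2500, 2500)])
        out = distance_to_features([line], grid)
        assert out.values[0, 0] == 0.0 and out.values[0, 2] == 0.0

    def test_nonnegative_everywhere(self, rng):
        grid = GridSpec(0, 5000, 1000, 5, 5, "local")
        lines = [LineString([(0, 0), (5000, 5000)])]
        assert (distance_to_features(lines, grid).values >= 0).all()

    def test_empty_geometry_set_rejected(self, grid_3x3):
        with pytest.raises(ValueError):
            distance_to_features([], grid_3x3)


class TestExclusion:
    def test_no_features_all_clear(self, grid_3x3):
        mask = build_exclusion_mask(grid_3x3)
        assert not mask.values.any()

    def test_airport_buffer_boundary(self):
        grid = GridSpec(0, 2000, 1.0, 1, 2000, "local")
        # airport at x=0 on the center row; centers at x+0.5 m steps
        airports = PointTable.from_xy([0.0], [1999.5], crs_id="local")
        mask = build_exclusion_mask(grid, airports=airports,
                                    airport_buffer_m=1000.0)
        centers_x = grid.cell_centers()[0][0]
        assert mask.values[0, np.argmin(np.abs(centers_x - 999.0))] == 1
        assert mask.values[0, np.argmin(np.abs(centers_x - 1001.0))] == 0

    def test_overlapping_polygons_union(self, grid_3x3):
        blob = Point(1500, 1500).buffer(800)
        mask = build_exclusion_mask(grid_3x3, military=[blob], protected=[blob])
        assert mask.values[1, 1] == 1
        assert mask.values.sum() == 1  # union, not double-count


class TestWeightedOverlay:
    def test_all_fours_give_printed_maximum(self, grid_3x3):
        rasters = _score_rasters(grid_3x3, dict.fromkeys(DEFAULT_WEIGHTS, 4))
        out = weighted_overlay(rasters)
        assert (out.score.values == 48).all()

    def test_all_zero_gives_zero(self, grid_3x3):
        rasters = _score_rasters(grid_3x3, dict.fromkeys(DEFAULT_WEIGHTS, 0))
        assert (weighted_overlay(rasters).score.values == 0).all()

    def test_hand_arithmetic_example(self, grid_3x3):
        scores = dict(zip(
            ["wind_power_class", "distance_to_roads", "distance_to_transmission",
             "landcover", "slope", "population_density"], [4, 3, 2, 1, 0, 4]))
        out = weighted_overlay(_score_rasters(grid_3x3, scores))
        assert (out.score.values == 28).all()  # 12+6+4+2+0+4

    def test_missing_criterion_rejected(self, grid_3x3):
        rasters = _score_rasters(grid_3x3, dict.fromkeys(DEFAULT_WEIGHTS, 2))
        del rasters["slope"]
        with pytest.raises(ValueError, match="slope"):
            weighted_overlay(rasters)

    def test_exclusion_and_nodata_become_nodata(self, grid_3x3):
        rasters = _score_rasters(grid_3x3, dict.fromkeys(DEFAULT_WEIGHTS, 3))
        rasters["slope"].values[0, 0] = -1
        mask = make_raster(grid_3x3, np.zeros((3, 3), dtype=np.int32),
                           nodata=-1, kind="ordinal")
        mask.values[2, 2] = 1
        out = weighted_overlay(rasters, exclusion_mask=mask)
        assert out.score.values[0, 0] == out.score.nodata
        assert out.score.values[2, 2] == out.score.nodata
        assert out.score.values[1, 1] == 3 * sum(DEFAULT_WEIGHTS.values())

    def test_matches_brute_force_cellwise_sum(self, rng):
        grid = GridSpec(0, 40_000, 1000, 40, 40, "local")
        rasters = {name: make_raster(grid, rng.integers(0, 5, grid.shape),
                                     nodata=-1, kind="ordinal")
                   for name in DEFAULT_WEIGHTS}
        out = weighted_overlay(rasters)
        rows = rng.integers(0, 40, 1000)
        cols = rng.integers(0, 40, 1000)
        for i, j in zip(rows, cols):
            expected = sum(w * rasters[n].values[i, j]
                           for n, w in DEFAULT_WEIGHTS.items())
            assert out.score.values[i, j] == expected

    def test_unit_bump_raises_total_by_weight(self, rng):
        grid = GridSpec(0, 10_000, 1000, 10, 10, "local")
        rasters = {name: make_raster(grid, rng.integers(0, 4, grid.shape),
                                     nodata=-1, kind="ordinal")
                   for name in DEFAULT_WEIGHTS}
        base = weighted_overlay(rasters).score.values
        bumped = {n: r for n, r in rasters.items()}
        bumped["landcover"] = make_raster(grid, rasters["landcover"].values + 1,
                                          nodata=-1, kind="ordinal")
        out = weighted_overlay(bumped).score.values
        np.testing.assert_array_equal(out - base, DEFAULT_WEIGHTS["landcover"])


class TestSitingClasses:
    @pytest.mark.parametrize("score,cls", [
        (0, SITING_LOW), (16, SITING_LOW), (17, SITING_MODERATE),
        (32, SITING_MODERATE), (33, SITING_HIGH), (48, SITING_HIGH),
    ])
    def test_class_bounds(self, grid_3x3, score, cls):
        rasters = _score_rasters(grid_3x3, dict.fromkeys(DEFAULT_WEIGHTS, 0))
        smap = weighted_overlay(rasters)
        smap.score.values[:] = score
        out = classify_siting(smap)
        assert (out.classes.values == cls).all()

    def test_out_of_range_rejected(self, grid_3x3):
        smap = weighted_overlay(_score_rasters(grid_3x3,
                                               dict.fromkeys(DEFAULT_WEIGHTS, 0)))
        smap.score.values[:] = 60
        with pytest.raises(ValueError):
            classify_siting(smap)

    def test_class_monotone_and_partition(self, rng, grid_small):
        rasters = {name: make_raster(grid_small, rng.integers(0, 5, grid_small.shape),
                                     nodata=-1, kind="ordinal")
                   for name in DEFAULT_WEIGHTS}
        smap = weighted_overlay(rasters)
        cmap = classify_siting(smap)
        s = smap.score.values.ravel()
        c = cmap.classes.values.ravel()
        order = np.argsort(s)
        assert (np.diff(c[order]) >= 0).all()
        assert set(np.unique(c)) <= {0, 1, 2}


class TestTurbineQuantile:
    def _score_map(self, grid, per_cell_scores):
        rasters = _score_rasters(grid, dict.fromkeys(DEFAULT_WEIGHTS, 0))
        smap = weighted_overlay(rasters)
        smap.score.values[:] = per_cell_scores
        return smap

    def test_toy_strict_count(self):
        grid = GridSpec(0, 1000, 1000, 1, 5, "test-plane")
        smap = self._score_map(grid, np.array([[10, 20, 31, 32, 40]]))
        turbines = PointTable.from_xy([500, 1500, 2500, 3500, 4500],
                                      [500] * 5, crs_id="test-plane")
        frac, n_nodata = turbine_score_quantile(turbines, smap, cutoff=32)
        assert frac == pytest.approx(0.6) and n_nodata == 0

    def test_all_on_max_cells(self, grid_3x3):
        smap = self._score_map(grid_3x3, 48)
        turbines = PointTable.from_xy([500, 1500], [500, 1500], crs_id="test-plane")
        assert turbine_score_quantile(turbines, smap, 32)[0] == 0.0

    def test_cutoff_zero_always_zero(self, grid_3x3, rng):
        smap = self._score_map(grid_3x3, rng.integers(0, 49, (3, 3)))
        turbines = PointTable.from_xy([500, 2500], [500, 2500], crs_id="test-plane")
        assert turbine_score_quantile(turbines, smap, 0)[0] == 0.0

    def test_nodata_and_outside_counted_separately(self, grid_3x3):
        smap = self._score_map(grid_3x3, 10)
        smap.score.values[0, 0] = -1
        turbines = PointTable.from_xy([500, 1500, -900], [2500, 1500, 500],
                                      crs_id="test-plane")
        frac, n_nodata = turbine_score_quantile(turbines, smap, 32)
        assert n_nodata == 2 and frac == 1.0


class TestDefaultCriteria:
    def test_tables_cover_synthetic_ranges(self):
        specs = default_criteria([1, 2, 3, 4, 5])
        assert set(specs) == set(DEFAULT_WEIGHTS)
        assert specs["landcover"].mapping[1] == 4
        assert specs["landcover"].mapping[5] == 0
        assert specs["wind_power_class"].mapping[7] == 4
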