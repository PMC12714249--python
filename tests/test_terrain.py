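import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from benthicmap.raster import Raster
from benthicmap.terrain import (
    FLAT_ASPECT,
    GEOMORPHON_CODES,
    TerrainLayer,
    TerrainParams,
    aggregate_to_coarse,
    aspect_to_components,
    compute_geomorphons,
    compute_mean_curvature,
    compute_slope_aspect,
    compute_vrm,
    one_hot_geomorphons,
)
from conftest import random_depth


def plane_depth(a: float, b: float, shape=(9, 9), cell=1.0) -> Raster:
    """depth = a*x + b*y (x east, y north)."""
    rows, cols = shape
    x = np.arange(cols) * cell
    y = (rows - 1 - np.arange(rows))[:, None] * cell
    return Raster(a * x[None, :] + b * y + 30.0, cell)


class TestSlopeAspect:
    def test_constant_depth_is_flat(self):
        slope, aspect = compute_slope_aspect(Raster(np.full((6, 6), 12.0), 2.0))
        interior = slope.masked()[1:-1, 1:-1]
        np.testing.assert_allclose(interior, 0.0)
        assert (aspect.masked()[1:-1, 1:-1] == FLAT_ASPECT).all()

    def test_eastward_deepening_unit_plane(self):
        # 1 m of extra depth per metre east: slope 45 deg, downslope due east
        slope, aspect = compute_slope_aspect(plane_depth(1.0, 0.0))
        np.testing.assert_allclose(slope.masked()[1:-1, 1:-1], 45.0, atol=1e-9)
        np.testing.assert_allclose(aspect.masked()[1:-1, 1:-1], 90.0, atol=1e-9)

    def test_northward_shallowing_plane(self):
        # depth decreases northward => seafloor rises north, downslope south
        slope, aspect = compute_slope_aspect(plane_depth(0.0, -0.5))
        np.testing.assert_allclose(
            slope.masked()[1:-1, 1:-1], math.degrees(math.atan(0.5)), atol=1e-9
        )
        np.testing.assert_allclose(aspect.masked()[1:-1, 1:-1], 180.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_cell_by_cell_horn_oracle(self, seed):
        depth = random_depth(seed)
        slope, aspect = compute_slope_aspect(depth)
        elev = -depth.values
        for r in range(1, 7):
            for c in range(1, 7):
                s_ref, a_ref = oracles.horn_cell(elev, r, c, depth.cell_size)
                assert slope.values[r, c] == pytest.approx(s_ref, abs=1e-10)
                assert aspect.values[r, c] == pytest.approx(a_ref, abs=1e-10)

    def test_border_cells_are_nodata(self):
        slope, _ = compute_slope_aspect(random_depth(3))
        assert not slope.valid_mask()[0, :].any()
        assert not slope.valid_mask()[:, -1].any()

    def test_all_nodata_raises(self):
        r = Raster(np.full((4, 4), np.nan), 1.0)
        with pytest.raises(ValueError):
            compute_slope_aspect(r)


class TestAspectComponents:
    @pytest.mark.parametrize(
        "aspect,north,east",
        [
            (0.0, 1.0, 0.0),
            (90.0, 0.0, 1.0),
            (225.0, -math.sqrt(2) / 2, -math.sqrt(2) / 2),
        ],
    )
    def test_unit_circle_identities(self, aspect, north, east):
        layer = TerrainLayer(np.full((3, 3), aspect), 1.0, name="aspect")
        n, e = aspect_to_components(layer)
        assert n.values[1, 1] == pytest.approx(north, abs=1e-12)
        assert e.values[1, 1] == pytest.approx(east, abs=1e-12)

    def test_flat_sentinel_maps_to_zero_not_trig_of_minus_one(self):
        layer = TerrainLayer(np.full((2, 2), FLAT_ASPECT), 1.0)
        n, e = aspect_to_components(layer)
        assert (n.values == 0).all() and (e.values == 0).all()

    def test_components_lie_on_unit_circle(self, rng):
        vals = rng.uniform(0, 360, size=(6, 6))
        n, e = aspect_to_components(TerrainLayer(vals, 1.0))
        np.testing.assert_allclose(n.values**2 + e.values**2, 1.0, atol=1e-12)


class TestCurvature:
    def test_any_plane_has_zero_curvature(self):
        for a, b in [(0.3, -0.7), (0, 0), (2, 1)]:
            curv = compute_mean_curvature(plane_depth(a, b))
            np.testing.assert_allclose(curv.masked()[1:-1, 1:-1], 0.0, atol=1e-9)

    def test_paraboloid_closed_form(self):
        # depth = x^2 + y^2 -> elevation dome; -2(D+E)*100 = +400 everywhere
        rows = cols = 7
        x = np.arange(cols, dtype=float)
        y = np.arange(rows, dtype=float)[:, None]
        depth = Raster(x[None, :] ** 2 + y**2, 1.0)
        curv = compute_mean_curvature(depth)
        np.testing.assert_allclose(curv.masked()[1:-1, 1:-1], 400.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_fit_oracle(self, seed):
        depth = random_depth(seed)
        curv = compute_mean_curvature(depth)
        elev = -depth.values
        for r in range(1, 7):
            for c in range(1, 7):
                ref = oracles.zt_curvature_cell(elev, r, c, depth.cell_size)
                assert curv.values[r, c] == pytest.approx(ref, abs=1e-9)


def layers_from_arrays(slope, aspect, cell=1.0):
    return (
        TerrainLayer(np.asarray(slope, float), cell, name="slope"),
        TerrainLayer(np.asarray(aspect, float), cell, name="aspect"),
    )


class TestVRM:
    def test_uniform_inclined_plane_is_zero(self):
        slope, aspect = layers_from_arrays(
            np.full((5, 5), 30.0), np.full((5, 5), 135.0)
        )
        vrm = compute_vrm(slope, aspect, TerrainParams())
        np.testing.assert_allclose(vrm.masked(), 0.0, atol=1e-12)

    def test_hand_computed_mixed_window(self):
        # 4 cells S=45,A=0; 4 cells S=45,A=180; centre flat:
        # resultant = 8*cos45 + 1, VRM = 1 - 6.65685/9
        s = np.full((3, 3), 45.0)
        a = np.zeros((3, 3))
        a[0, :] = 0.0
        a[2, :] = 180.0
        a[1, 0] = 0.0
        a[1, 2] = 180.0
        s[1, 1] = 0.0
        a[1, 1] = FLAT_ASPECT
        slope, aspect = layers_from_arrays(s, a)
        vrm = compute_vrm(slope, aspect, TerrainParams())
        expected = 1 - (8 * math.cos(math.radians(45)) + 1) / 9
        assert vrm.values[1, 1] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.26035, abs=1e-4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_on_any_input(self, seed):
        g = np.random.default_rng(seed)
        slope, aspect = layers_from_arrays(
            g.uniform(0, 89, (6, 6)), g.uniform(0, 360, (6, 6))
        )
        vrm = compute_vrm(slope, aspect, TerrainParams())
        assert np.nanmin(vrm.masked()) >= 0.0
        assert np.nanmax(vrm.masked()) <= 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_cell_oracle(self, seed):
        g = np.random.default_rng(100 + seed)
        s = g.uniform(0, 80, (7, 7))
        a = g.uniform(0, 360, (7, 7))
        a[g.random((7, 7)) < 0.2] = FLAT_ASPECT
        s[a == FLAT_ASPECT] = 0.0
        slope, aspect = layers_from_arrays(s, a)
        vrm = compute_vrm(slope, aspect, TerrainParams())
        for r in range(7):
            for c in range(7):
                ref = oracles.vrm_cell(s, a, r, c, 3)
                assert vrm.values[r, c] == pytest.approx(ref, abs=1e-10)

    def test_perturbation_increases_ruggedness(self):
        base_s = np.full((5, 5), 20.0)
        base_a = np.full((5, 5), 90.0)
        prev = -1.0
        for jitter in (0.0, 5.0, 15.0, 40.0):
            a = base_a.copy()
            a[::2, ::2] = 90.0 + jitter
            slope, aspect = layers_from_arrays(base_s, a)
            v = compute_vrm(slope, aspect, TerrainParams()).values[2, 2]
            assert v >= prev
            prev = v

    def test_window_larger_than_grid_rejected(self):
        slope, aspect = layers_from_arrays(np.zeros((3, 3)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            compute_vrm(slope, aspect, TerrainParams(vrm_window=5))


class TestGeomorphons:
    def test_constant_depth_is_all_flat(self):
        gm = compute_geomorphons(Raster(np.full((12, 12), 20.0), 1.0),
                                 TerrainParams())
        assert (gm.values == GEOMORPHON_CODES["flat"]).all()

    def test_conical_shoal_apex_is_ridge(self):
        rows = cols = 21
        y, x = np.mgrid[0:rows, 0:cols]
        cone = np.hypot(y - 10, x - 10)  # depth grows away from the apex
        gm = compute_geomorphons(Raster(20.0 + cone, 1.0), TerrainParams())
        assert gm.values[10, 10] == GEOMORPHON_CODES["ridge"]

    def test_v_trench_floor_is_valley(self):
        rows = cols = 21
        x = np.arange(cols, dtype=float)
        depth = 30.0 - np.abs(x - 10)[None, :] * np.ones((rows, 1))
        gm = compute_geomorphons(Raster(depth, 1.0), TerrainParams())
        assert (gm.values[5:-5, 10] == GEOMORPHON_CODES["valley"]).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_line_of_sight_oracle(self, seed):
        g = np.random.default_rng(200 + seed)
        depth = Raster(25 + 4 * g.standard_normal((32, 32)), 2.0)
        params = TerrainParams(geomorphon_lookup=5)
        gm = compute_geomorphons(depth, params)
        elev = -depth.values
        for r in range(32):
            for c in range(32):
                ref = oracles.geomorphon_cell(
                    elev, r, c, 2.0, 5, params.flatness_angle
                )
                assert gm.values[r, c] == ref, (r, c)


class TestOneHot:
    def test_all_flat_input(self):
        gm = TerrainLayer(np.full((4, 4), float(GEOMORPHON_CODES["flat"])), 1.0)
        layers = one_hot_geomorphons(gm)
        by_name = {l.name: l for l in layers}
        assert (by_name["flat"].values == 1).all()
        for name in ("ridge", "shoulder", "slope_gm", "footslope", "valley"):
            assert (by_name[name].values == 0).all()

    def test_layers_partition_valid_cells(self, rng):
        codes = rng.integers(1, 7, size=(10, 10)).astype(float)
        codes[0, 0] = np.nan
        gm = TerrainLayer(codes, 1.0)
        layers = one_hot_geomorphons(gm)
        total = np.nansum([l.masked() for l in layers], axis=0)
        assert total[0, 0] == 0  # nodata propagates
        assert (total.ravel()[1:] == 1).all()

    def test_unknown_code_rejected(self):
        gm = TerrainLayer(np.full((2, 2), 99.0), 1.0)
        with pytest.raises(ValueError):
            one_hot_geomorphons(gm)


class TestAggregation:
    def test_constant_layer_stays_constant(self):
        layer = Raster(np.full((12, 12), 3.5), 5.0)
        coarse = aggregate_to_coarse(layer, 30.0)
        assert coarse.shape == (2, 2)
        np.testing.assert_allclose(coarse.values, 3.5)

    def test_six_by_six_block_mean(self):
        layer = Raster(np.arange(1, 37, dtype=float).reshape(6, 6), 5.0)
        coarse = aggregate_to_coarse(layer, 30.0)
        assert coarse.shape == (1, 1)
        assert coarse.values[0, 0] == pytest.approx(18.5)

    def test_one_hot_majority_rule(self):
        vals = np.zeros((6, 6))
        vals.ravel()[:20] = 1.0  # 20/36 >= 0.5
        coarse = aggregate_to_coarse(Raster(vals, 5.0), 30.0, categorical=True)
        assert coarse.values[0, 0] == 1.0
        vals.ravel()[:20] = 0.0
        vals.ravel()[:17] = 1.0  # 17/36 < 0.5
        coarse = aggregate_to_coarse(Raster(vals, 5.0), 30.0, categorical=True)
        assert coarse.values[0, 0] == 0.0

    def test_global_mean_preserved_when_ratio_integer(self, rng):
        layer = Raster(rng.normal(size=(24, 18)), 5.0)
        coarse = aggregate_to_coarse(layer, 30.0)
        assert coarse.values.mean() == pytest.approx(layer.values.mean())

    def test_non_integer_ratio_cell_centre_membership(self, rng):
        # 4 m cells into 30 m cells: 7.5 fine cells per coarse cell
        vals = rng.normal(size=(15, 15))
        coarse = aggregate_to_coarse(Raster(vals, 4.0), 30.0)
        assert coarse.shape == (2, 2)
        # rows 0..6 have centres < 30 m, rows 7..14 beyond
        assert coarse.values[0, 0] == pytest.approx(vals[:7, :7].mean())
        assert coarse.values[1, 1] == pytest.approx(vals[7:, 7:].mean())

    def test_empty_coarse_cells_are_nodata(self):
        vals = np.full((12, 12), np.nan)
        vals[:6, :6] = 1.0
        coarse = aggregate_to_coarse(Raster(vals, 5.0), 30.0)
        assert coarse.valid_mask()[0, 0]
        assert not coarse.valid_mask()[1, 1]
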