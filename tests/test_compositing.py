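"""Seasonal compositing: brute-force medoid oracles, closed-form
statistics, SAR covariates, Lee filter and terrain derivatives."""

import datetime as dt
import itertools

import numpy as np
import pytest

from annualcover.compositing import (
    DRY,
    SeasonDefinition,
    WET,
    lee_filter,
    medoid_composite,
    partition_by_season,
    percentile_medoid_composite,
    sar_seasonal_covariates,
    stddev_composite,
    terrain_covariates,
)
from annualcover.grid import CLOUD, GridSpec, NODATA, SARScene, new_mask
from tests.conftest import make_scene


def one_band_scenes(values, grid, band="Bred"):
    """One scene per value, constant over the grid."""
    return [
        make_scene({band: v}, grid, date=dt.date(2020, 5, 1 + i))
        for i, v in enumerate(values)
    ]


def brute_force_medoid(vectors):
    """Independent oracle: exhaustive distance-sum minimization."""
    best, best_sum = None, np.inf
    for i, x in enumerate(vectors):
        s = sum(np.linalg.norm(np.asarray(x) - np.asarray(y)) for y in vectors)
        if s < best_sum - 1e-15:
            best, best_sum = i, s
    return vectors[best]


class TestSeasonPartition:
    def test_may_is_dry_of_its_year(self):
        assert SeasonDefinition().season_of(dt.date(2020, 5, 15)) == (DRY, 2020)

    def test_january_belongs_to_previous_wet_season(self):
        assert SeasonDefinition().season_of(dt.date(2020, 1, 20)) == (WET, 2019)

    def test_twelve_monthly_scenes_split_six_six(self, small_grid):
        scenes = [
            make_scene({"Bred": 0.1}, small_grid, date=dt.date(2020, m, 10))
            for m in range(1, 13)
        ]
        buckets = partition_by_season(scenes)
        n_dry = sum(len(v) for (s, _), v in buckets.items() if s == DRY)
        n_wet = sum(len(v) for (s, _), v in buckets.items() if s == WET)
        assert (n_dry, n_wet) == (6, 6)
        assert sum(len(v) for v in buckets.values()) == 12

    def test_seasons_must_partition_the_year(self):
        with pytest.raises(ValueError):
            SeasonDefinition(frozenset({4, 5}), frozenset({10, 11}))


class TestMedoid:
    def test_single_scene_is_its_own_medoid(self, small_grid):
        rng = np.random.default_rng(0)
        scene = make_scene(
            {b: rng.uniform(0, 1, small_grid.shape)
             for b in ("Bblue", "Bgreen", "Bred", "Bnir", "Bswir1", "Bswir2")},
            small_grid,
        )
        comp = medoid_composite([scene])
        np.testing.assert_array_equal(comp.layers["medoid_Bred"], scene.bands["Bred"])

    def test_three_observation_oracle(self, small_grid):
        comp = medoid_composite(
            one_band_scenes([0.1, 0.2, 0.9], small_grid), bands=("Bred",)
        )
        assert comp.layers["medoid_Bred"][0, 0] == pytest.approx(0.2)

    def test_matches_brute_force_on_random_stacks(self, small_grid):
        """Multi-band medoid equals the exhaustive oracle pixel by pixel."""
        rng = np.random.default_rng(7)
        bands = ("Bred", "Bnir")
        scenes = [
            make_scene(
                {b: rng.uniform(0, 1, small_grid.shape) for b in bands},
                small_grid, date=dt.date(2020, 5, 1 + i),
            )
            for i in range(5)
        ]
        comp = medoid_composite(scenes, bands=bands)
        for r, c in itertools.product(range(3), range(3)):
            vectors = [
                tuple(s.bands[b][r, c] for b in bands) for s in scenes
            ]
            expected = brute_force_medoid(vectors)
            got = tuple(comp.layers["medoid_" + b][r, c] for b in bands)
            assert got == pytest.approx(expected)

    def test_medoid_membership_property(self, small_grid):
        """Every composited pixel vector is one of the input vectors."""
        rng = np.random.default_rng(8)
        bands = ("Bred", "Bnir")
        scenes = [
            make_scene(
                {b: rng.uniform(0, 1, small_grid.shape) for b in bands},
                small_grid, date=dt.date(2020, 5, 1 + i),
            )
            for i in range(4)
        ]
        comp = medoid_composite(scenes, bands=bands)
        for r, c in itertools.product(range(8), range(8)):
            got = tuple(comp.layers["medoid_" + b][r, c] for b in bands)
            options = {
                tuple(s.bands[b][r, c] for b in bands) for s in scenes
            }
            assert got in options

    def test_permutation_invariance(self, small_grid):
        rng = np.random.default_rng(9)
        scenes = [
            make_scene({"Bred": rng.uniform(0, 1, small_grid.shape)},
                       small_grid, date=dt.date(2020, 5, 1 + i))
            for i in range(5)
        ]
        a = medoid_composite(scenes, bands=("Bred",)).layers["medoid_Bred"]
        b = medoid_composite(scenes[::-1], bands=("Bred",)).layers["medoid_Bred"]
        np.testing.assert_array_equal(a, b)

    def test_fully_masked_scene_changes_nothing(self, small_grid):
        scenes = one_band_scenes([0.1, 0.2, 0.9], small_grid)
        cloudy = make_scene({"Bred": 0.5}, small_grid,
                            date=dt.date(2020, 7, 1),
                            mask=new_mask(small_grid, CLOUD))
        a = medoid_composite(scenes, bands=("Bred",)).layers["medoid_Bred"]
        b = medoid_composite(scenes + [cloudy], bands=("Bred",)).layers["medoid_Bred"]
        np.testing.assert_array_equal(a, b)

    def test_no_valid_observation_gives_nan(self, small_grid):
        cloudy = make_scene({"Bred": 0.5}, small_grid,
                            mask=new_mask(small_grid, NODATA))
        comp = medoid_composite([cloudy], bands=("Bred",))
        assert np.isnan(comp.layers["medoid_Bred"]).all()
        assert (comp.valid_count == 0).all()

    def test_empty_scene_list_errors(self):
        with pytest.raises(ValueError):
            medoid_composite([])


class TestPercentileMedoid:
    @pytest.mark.parametrize("q,expected", [(20, 0.2), (80, 0.4)])
    def test_five_observation_nearest_rank_oracle(self, small_grid, q, expected):
        scenes = one_band_scenes([0.1, 0.2, 0.3, 0.4, 0.5], small_grid)
        comp = percentile_medoid_composite(scenes, bands=("Bred",), q=q)
        assert comp.layers[f"p{q}_Bred"][0, 0] == pytest.approx(expected)

    def test_identical_observations_return_that_value(self, small_grid):
        scenes = one_band_scenes([0.3, 0.3, 0.3], small_grid)
        comp = percentile_medoid_composite(scenes, bands=("Bred",), q=20)
        assert comp.layers["p20_Bred"][0, 0] == pytest.approx(0.3)

    def test_few_observations_fall_back_to_plain_medoid(self, small_grid):
        scenes = one_band_scenes([0.1, 0.9], small_grid)
        comp = percentile_medoid_composite(scenes, bands=("Bred",), q=80)
        plain = medoid_composite(scenes, bands=("Bred",))
        np.testing.assert_array_equal(
            comp.layers["p80_Bred"], plain.layers["medoid_Bred"]
        )

    def test_q_out_of_range_errors(self, small_grid):
        scenes = one_band_scenes([0.1, 0.2, 0.3], small_grid)
        with pytest.raises(ValueError):
            percentile_medoid_composite(scenes, bands=("Bred",), q=100)


class TestStdDev:
    def test_constant_stack_is_zero(self, small_grid):
        comp = stddev_composite(one_band_scenes([0.4, 0.4, 0.4], small_grid),
                                bands=("Bred",))
        np.testing.assert_allclose(comp.layers["std_Bred"], 0.0, atol=1e-12)

    def test_two_point_closed_form(self, small_grid):
        comp = stddev_composite(one_band_scenes([0.1, 0.3], small_grid),
                                bands=("Bred",))
        assert comp.layers["std_Bred"][0, 0] == pytest.approx(0.1)

    def test_three_point_closed_form(self, small_grid):
        comp = stddev_composite(one_band_scenes([0.1, 0.2, 0.3], small_grid),
                                bands=("Bred",))
        assert comp.layers["std_Bred"][0, 0] == pytest.approx(
            np.sqrt(2.0 / 3.0) * 0.1
        )

    def test_single_observation_reports_zero(self, small_grid):
        comp = stddev_composite(one_band_scenes([0.5], small_grid), bands=("Bred",))
        np.testing.assert_array_equal(comp.layers["std_Bred"], 0.0)


def sar_scene(vv, vh, grid, orbit="ascending", day=1):
    shape = grid.shape
    return SARScene(
        vv=np.full(shape, float(vv)),
        vh=np.full(shape, float(vh)),
        orbit=orbit,
        date=dt.date(2020, 6, day),
        mask=new_mask(grid),
        grid=grid,
    )


class TestSARCovariates:
    def test_single_scene_polarization_difference(self, small_grid):
        comp = sar_seasonal_covariates([sar_scene(-10, -16, small_grid)])
        assert comp.layers["nd_VHVV"][0, 0] == pytest.approx(
            (-16 - (-10)) / (-16 + (-10))
        )
        assert comp.layers["nd_VHVV"][0, 0] == pytest.approx(0.23077, abs=1e-5)

    def test_equal_polarizations_give_zero_difference(self, small_grid):
        comp = sar_seasonal_covariates([sar_scene(-12, -12, small_grid)])
        np.testing.assert_allclose(comp.layers["nd_VHVV"], 0.0)

    def test_two_scene_mean(self, small_grid):
        comp = sar_seasonal_covariates(
            [sar_scene(-8, -14, small_grid, day=1),
             sar_scene(-12, -18, small_grid, day=2)]
        )
        np.testing.assert_allclose(comp.layers["mean_VV"], -10.0)

    def test_vanishing_denominator_is_nodata(self, small_grid):
        comp = sar_seasonal_covariates([sar_scene(-5, 5, small_grid)])
        assert np.isnan(comp.layers["nd_VHVV"]).all()

    def test_mixed_orbits_kept_as_separate_layers(self, small_grid):
        comp = sar_seasonal_covariates(
            [sar_scene(-8, -14, small_grid, orbit="ascending"),
             sar_scene(-12, -18, small_grid, orbit="descending")]
        )
        assert "mean_VV_asce" in comp.layers and "mean_VV_desc" in comp.layers


class TestLeeFilter:
    def test_constant_image_unchanged(self, small_grid):
        scene = sar_scene(-10, -15, small_grid)
        out = lee_filter(scene, window=3)
        np.testing.assert_allclose(out.vv, scene.vv)
        np.testing.assert_allclose(out.vh, scene.vh)

    def test_zero_noise_variance_returns_input(self, small_grid):
        rng = np.random.default_rng(5)
        scene = sar_scene(-10, -15, small_grid)
        scene.vv += rng.normal(0, 1, small_grid.shape)
        out = lee_filter(scene, window=3, noise_var=0.0)
        np.testing.assert_allclose(out.vv, scene.vv)

    def test_speckle_spike_amplitude_reduced(self):
        grid = GridSpec(0, 0, 30, 5, 5)
        scene = sar_scene(-10, -15, grid)
        scene.vv[2, 2] = 5.0  # isolated bright spike
        out = lee_filter(scene, window=3)
        assert out.vv[2, 2] < scene.vv[2, 2]
        assert out.vv[2, 2] > -10.0

    def test_even_window_rejected(self, small_grid):
        with pytest.raises(ValueError):
            lee_filter(sar_scene(-10, -15, small_grid), window=4)


class TestTerrain:
    def test_flat_dem_has_zero_slope(self, small_grid):
        comp = terrain_covariates(np.full(small_grid.shape, 100.0), small_grid)
        np.testing.assert_allclose(comp.layers["slope"], 0.0)
        assert np.isnan(comp.layers["aspect"]).all()

    def test_east_rising_plane_slope_and_aspect(self):
        grid = GridSpec(0, 0, 30, 6, 6)
        cols = np.arange(6, dtype=float)
        dem = np.tile(cols, (6, 1))  # +1 m per 30 m pixel, rising east
        comp = terrain_covariates(dem, grid)
        interior = comp.layers["slope"][1:-1, 1:-1]
        np.testing.assert_allclose(
            interior, np.degrees(np.arctan(1 / 30)), atol=1e-9
        )
        # downslope points west
        np.testing.assert_allclose(
            comp.layers["aspect"][1:-1, 1:-1], 270.0, atol=1e-9
        )

    def test_north_tilted_plane_aspect_zero(self):
        grid = GridSpec(0, 0, 30, 6, 6)
        rows = np.arange(6, dtype=float)
        dem = np.tile(rows[:, None], (1, 6))  # rises southward
        comp = terrain_covariates(dem, grid)
        np.testing.assert_allclose(
            comp.layers["aspect"][1:-1, 1:-1], 0.0, atol=1e-9
        )

    def test_tiny_grid_rejected(self):
        grid = GridSpec(0, 0, 30, 2, 2)
        with pytest.raises(ValueError):
            terrain_covariates(np.zeros((2, 2)), grid)
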