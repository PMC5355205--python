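"""Synthetic landscape generator: terrain, burns, weather, forage truth."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tallgrass as tg
from tallgrass.landscape import (
    ForageTruthParams,
    derive_slope_aspect,
    forage_truth,
    generate_burn_history,
    generate_shrub_mask,
    generate_terrain,
    generate_weather,
    sample_plots,
    WeatherParams,
)


class TestTerrain:
    def test_same_seed_is_bit_identical(self):
        a = generate_terrain(20, 30, seed=5)
        b = generate_terrain(20, 30, seed=5)
        assert np.array_equal(a.elevation.data, b.elevation.data)
        assert np.array_equal(a.aspect.data, b.aspect.data)

    def test_relief_amplitude_bounds_elevation_range(self):
        t = generate_terrain(50, 50, relief_amplitude=50.0, seed=3)
        assert np.ptp(t.elevation.data) <= 50.0 + 1e-9

    def test_grids_share_georeferencing(self):
        t = generate_terrain(15, 25, seed=1)
        assert t.elevation.shape == t.slope.shape == t.aspect.shape
        assert t.elevation.cell_size == t.slope.cell_size

    def test_rejects_tiny_grids(self):
        with pytest.raises(ValueError):
            generate_terrain(2, 10, seed=0)

    def test_terrain_invariants(self):
        t = generate_terrain(40, 40, seed=9)
        assert np.all((t.slope.data >= 0) & (t.slope.data < 90))
        assert np.all((t.aspect.data >= 0) & (t.aspect.data < 2 * np.pi))


class TestSlopeAspect:
    def test_flat_surface_has_zero_slope_neutral_aspect(self):
        slope, aspect = derive_slope_aspect(np.full((5, 5), 380.0), 10.0)
        assert np.all(slope == 0)
        assert np.allclose(np.cos(aspect), 0.0)

    @pytest.mark.parametrize(
        "gx,gy,cos_aspect_expected",
        [
            (0.0, 0.1, -1.0),   # dips due south (elevation rises northward)
            (-0.1, 0.0, 0.0),   # dips due east
            (0.1, 0.0, 0.0),    # dips due west
        ],
    )
    def test_analytic_plane(self, gx, gy, cos_aspect_expected):
        cs = 10.0
        y, x = np.mgrid[0:8, 0:8] * cs
        z = 400.0 + gx * x + gy * y
        slope, aspect = derive_slope_aspect(z, cs)
        grad = np.hypot(gx, gy)
        assert np.allclose(slope, np.degrees(np.arctan(grad)), atol=1e-9)
        assert np.allclose(np.cos(aspect), cos_aspect_expected, atol=1e-9)

    @given(
        gx=st.floats(-0.3, 0.3),
        gy=st.floats(-0.3, 0.3),
    )
    @settings(max_examples=40, deadline=None)
    def test_affine_surface_gradient_recovered(self, gx, gy):
        """Horn differences are exact on affine elevation surfaces."""
        cs = 10.0
        y, x = np.mgrid[0:6, 0:6] * cs
        slope, aspect = derive_slope_aspect(400.0 + gx * x + gy * y, cs)
        expected = np.degrees(np.arctan(np.hypot(gx, gy)))
        assert np.allclose(slope, expected, rtol=1e-6, atol=1e-9)

    def test_rejects_single_row(self):
        with pytest.raises(ValueError):
            derive_slope_aspect(np.ones((1, 9)), 10.0)


class TestBurnHistory:
    def test_annual_interval_burns_every_year(self):
        years = list(range(2007, 2014))
        b = generate_burn_history((10, 40), [1, 2, 4, 20], years, seed=2)
        annual = b.watersheds[0]
        assert len(annual.burn_dates) == 7

    def test_twenty_year_interval_burns_at_most_once(self):
        years = list(range(2007, 2014))
        b = generate_burn_history((10, 40), [1, 2, 4, 20], years, seed=2)
        assert len(b.watersheds[3].burn_dates) <= 1

    def test_days_since_burn_zero_on_burn_date(self):
        b = generate_burn_history((10, 40), [1], [2011], seed=4)
        w = b.watersheds[0]
        assert w.days_since_burn(w.burn_dates[0]) == 0.0

    def test_burn_dates_in_spring_window(self):
        b = generate_burn_history((10, 40), [1, 2], list(range(2007, 2014)), seed=6)
        for w in b.watersheds:
            for d in w.burn_dates:
                assert dt.date(d.year, 3, 15) <= d <= dt.date(d.year, 5, 5)

    def test_days_since_burn_nonnegative_all_season(self):
        b = generate_burn_history((10, 40), [1, 2, 4, 20], [2011], seed=6)
        for day in range(0, 183, 14):
            g = b.days_since_burn_grid(dt.date(2011, 4, 1) + dt.timedelta(days=day))
            assert np.all(g >= 0)

    def test_unknown_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            generate_burn_history((10, 40), [3], [2011], seed=0)


class TestWeather:
    def test_cumulative_precip_nondecreasing_within_year(self):
        w = generate_weather([2011], seed=1)
        season = w.daily[(w.daily["date"] >= "2011-03-01")]
        assert season["cum_precip_mm"].is_monotonic_increasing

    def test_cumulative_precip_resets_at_march_first(self):
        w = generate_weather([2011, 2012], seed=1)
        mar1 = w.cum_precip(dt.date(2012, 3, 1))
        feb28 = float(
            w.daily[w.daily["date"] == "2012-02-28"]["cum_precip_mm"].iloc[0]
        )
        assert mar1 < feb28

    def test_long_run_mean_matches_configured_total(self):
        """Monte-Carlo check: 200 non-drought years average within 5% of 835 mm."""
        years = list(range(1900, 2100))
        w = generate_weather(years, seed=3)
        means = [w.annual_precip(y) for y in years]
        assert abs(np.mean(means) - 835.0) / 835.0 < 0.05

    def test_drought_year_has_lower_anpp(self):
        w = generate_weather([2011, 2012], drought_years=[2012], seed=5)
        assert w.anpp(2012) < w.anpp(2011)
        assert w.anpp(2012) > 0

    def test_negative_precip_param_rejected(self):
        with pytest.raises(ValueError):
            generate_weather([2011], WeatherParams(mean_annual_precip_mm=-5), seed=0)


class TestForageTruth:
    def test_protein_declines_with_time_since_burn(self):
        p0, _ = forage_truth(400, 2, -1, 0, 200, 150)
        p120, _ = forage_truth(400, 2, -1, 120, 200, 150)
        assert p0 > p120

    def test_biomass_increases_with_precipitation(self):
        _, b0 = forage_truth(400, 2, -1, 60, 0, 180)
        _, b300 = forage_truth(400, 2, -1, 60, 300, 180)
        assert b300 > b0

    def test_deterministic_at_zero_noise(self):
        a = forage_truth(395, 3, 0.5, 40, 180, 160)
        b = forage_truth(395, 3, 0.5, 40, 180, 160)
        assert a == b

    def test_negative_days_since_burn_rejected(self):
        with pytest.raises(ValueError):
            forage_truth(400, 2, -1, -1, 200, 150)

    def test_monotonicity_grid_sweep(self):
        """Stated monotonicities hold across a 10×10×5 covariate sweep:
        protein falls with time-since-burn and rises with elevation;
        biomass rises with precipitation and falls with elevation."""
        dsb = np.linspace(0, 400, 10)
        precip = np.linspace(20, 500, 10)
        elev = np.linspace(380, 430, 5)
        D, P, E = np.meshgrid(dsb, precip, elev, indexing="ij")
        prot, bio = forage_truth(E, 2.0, 0.0, D, P, 180.0)
        assert np.all(np.diff(prot, axis=0) < 0), "protein must fall with days-since-burn"
        assert np.all(np.diff(bio, axis=1) > 0), "biomass must rise with cumulative precip"
        assert np.all(np.diff(prot, axis=2) > 0), "protein must rise with elevation"
        assert np.all(np.diff(bio, axis=2) < 0), "biomass must fall with elevation"


class TestSamplePlots:
    def test_noiseless_plots_recover_calibration_exactly(self, small_landscape):
        terrain, burns, weather = small_landscape
        _, bio = sample_plots(
            terrain, burns, weather, [2012], 40, 40,
            protein_noise_sd=0.0, height_noise_cm=0.0,
            calibrations={2012: (2.40, 3.70)}, seed=8,
        )
        cal = tg.fit_disk_calibration(bio["height_cm"], bio["biomass"])
        assert cal.slope == pytest.approx(2.40, abs=1e-9)
        assert cal.intercept == pytest.approx(3.70, abs=1e-9)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_requested_counts_and_fields(self, small_landscape):
        terrain, burns, weather = small_landscape
        prot, bio = sample_plots(terrain, burns, weather, [2011], 60, 45, seed=9)
        assert len(prot) == 60 and len(bio) == 45
        for col in ("elevation", "slope", "cos_aspect", "days_since_burn",
                    "cum_precip", "burns_since_1980", "protein"):
            assert prot[col].notna().all()

    def test_seeded_runs_identical(self, small_landscape):
        terrain, burns, weather = small_landscape
        a = sample_plots(terrain, burns, weather, [2011], 40, 40, seed=4)
        b = sample_plots(terrain, burns, weather, [2011], 40, 40, seed=4)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_minimum_plot_count_enforced(self, small_landscape):
        terrain, burns, weather = small_landscape
        with pytest.raises(ValueError):
            sample_plots(terrain, burns, weather, [2011], 10, 40, seed=0)


def test_shrub_mask_fraction_and_shape():
    m = generate_shrub_mask((50, 50), fraction=0.1, seed=2)
    assert m.mask.shape == (50, 50)
    assert 0.05 < m.mask.mean() < 0.15
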