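"""Wet-bulb formula, thresholds, exposure accounting and aggregation."""

import mpmath as mp
import numpy as np
import pytest
import xarray as xr

from irriheat import heat_exposure as hx
from irriheat.errors import (
    ConfigurationError,
    DomainError,
    EmptySelectionError,
    InputError,
)


def stull_oracle(t2m: float, rh: float) -> float:
    """Independent high-precision evaluation of the wet-bulb fit."""
    with mp.workdps(40):
        t, phi = mp.mpf(t2m), mp.mpf(rh)
        return float(
            t * mp.atan(mp.mpf("0.151977") * mp.sqrt(phi + mp.mpf("8.313659")))
            + mp.atan(t + phi) - mp.atan(phi - mp.mpf("1.676331"))
            + mp.mpf("0.00391838") * phi ** mp.mpf("1.5")
            * mp.atan(mp.mpf("0.023101") * phi)
            - mp.mpf("4.68035")
        )


class TestWetBulb:
    @pytest.mark.parametrize(
        "t2m, rh, expected",
        [
            (20.0, 50.0, 13.70502696898814),   # frozen from stull_oracle
            (35.0, 80.0, 31.935527930311184),
        ],
    )
    def test_frozen_oracle_values(self, t2m, rh, expected):
        assert hx.wet_bulb(t2m, rh) == pytest.approx(expected, abs=1e-9)
        assert stull_oracle(t2m, rh) == pytest.approx(expected, abs=1e-12)

    def test_elementwise_purity(self):
        field = np.full((4, 5), 25.0)
        out = hx.wet_bulb(field, np.full((4, 5), 60.0))
        np.testing.assert_allclose(out, out.flat[0])

    def test_below_air_temperature_when_unsaturated(self):
        t = np.linspace(5, 50, 60)[:, None]
        phi = np.linspace(10, 95, 60)[None, :]
        assert np.all(hx.wet_bulb(t, phi) < t)

    def test_monotone_in_both_arguments(self):
        t = np.linspace(5, 50, 50)[:, None]
        phi = np.linspace(5, 100, 50)[None, :]
        tw = hx.wet_bulb(t, phi)
        assert np.all(np.diff(tw, axis=0) > 0)
        assert np.all(np.diff(tw, axis=1) > 0)

    def test_domain_error_on_nonpositive_humidity(self):
        with pytest.raises(DomainError):
            hx.wet_bulb(20.0, 0.0)
        with pytest.raises(DomainError):
            hx.wet_bulb(20.0, -5.0)


def _toy_cube(values, years):
    """(time,) values replicated over a 2x2 grid with a year coord."""
    values = np.asarray(values, dtype=float)
    data = np.tile(values[:, None, None], (1, 2, 2))
    return xr.DataArray(
        data, dims=("time", "lat", "lon"),
        coords={"time": np.arange(values.size),
                "year": ("time", years),
                "lat": [0, 1], "lon": [0, 1]},
    )


class TestThreshold:
    def test_order_statistic_bracketing(self):
        vals = np.arange(1.0, 101.0)
        pool = _toy_cube(vals, np.zeros(100, dtype=int))
        thr = hx.reference_threshold(pool, q=99)
        assert float(vals[98]) <= float(thr.min()) <= float(vals[99])

    def test_constant_pool_no_exceedance(self):
        pool = _toy_cube(np.full(50, 7.0), np.zeros(50, dtype=int))
        thr = hx.reference_threshold(pool)
        assert float(thr.max()) == 7.0
        hours = hx.exceedance_hours(pool, thr)
        assert float(hours.sum()) == 0.0

    def test_tail_mass_on_defining_sample(self):
        rng = np.random.default_rng(0)
        n = 20000
        pool = _toy_cube(rng.normal(size=n), np.zeros(n, dtype=int))
        thr = hx.reference_threshold(pool, q=99)
        frac = float((pool > thr).mean("time").isel(lat=0, lon=0))
        assert frac == pytest.approx(0.01, abs=1.0 / np.sqrt(n))

    def test_empty_pool_rejected(self):
        with pytest.raises(InputError):
            hx.reference_threshold(_toy_cube(np.array([]), np.array([])))


class TestExceedance:
    def test_two_exceeding_blocks_give_six_hours(self):
        cube = _toy_cube([1.0, 5.0, 6.0, 2.0], np.zeros(4, dtype=int))
        thr = xr.zeros_like(cube.isel(time=0, drop=True)) + 4.0
        hours = hx.exceedance_hours(cube, thr)
        np.testing.assert_allclose(hours.sel(year=0), 6.0)

    def test_saturation_at_full_noleap_year(self):
        n = 2920
        cube = _toy_cube(np.random.default_rng(1).normal(size=n),
                         np.zeros(n, dtype=int))
        thr = xr.zeros_like(cube.isel(time=0, drop=True)) - np.inf
        hours = hx.exceedance_hours(cube, thr)
        np.testing.assert_allclose(hours, hx.HOURS_PER_YEAR)

    def test_grouped_by_year(self):
        cube = _toy_cube([10.0, 0.0, 10.0, 10.0],
                         np.array([2000, 2000, 2001, 2001]))
        thr = xr.zeros_like(cube.isel(time=0, drop=True)) + 5.0
        hours = hx.exceedance_hours(cube, thr)
        np.testing.assert_allclose(hours.sel(year=2000), 3.0)
        np.testing.assert_allclose(hours.sel(year=2001), 6.0)

    def test_grid_mismatch_rejected(self):
        cube = _toy_cube([1.0, 2.0], np.zeros(2, dtype=int))
        thr = xr.DataArray(np.zeros((3, 3)), dims=("lat", "lon"))
        with pytest.raises(InputError):
            hx.exceedance_hours(cube, thr)


def _exposure(data):
    data = np.asarray(data, dtype=float)
    return xr.DataArray(
        data, dims=("member", "year", "lat", "lon"),
        coords={"member": np.arange(data.shape[0]),
                "year": 2000 + np.arange(data.shape[1])},
    )


class TestImpact:
    def test_identity_gives_zero_field(self):
        a = _exposure(np.random.default_rng(2).uniform(0, 100, (3, 4, 2, 2)))
        np.testing.assert_allclose(hx.impact_difference(a, a), 0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = _exposure(rng.uniform(0, 100, (3, 4, 2, 2)))
        b = _exposure(rng.uniform(0, 100, (3, 4, 2, 2)))
        np.testing.assert_allclose(hx.impact_difference(a, b).values,
                                   -hx.impact_difference(b, a).values,
                                   atol=1e-12)

    def test_linearity_through_intermediate(self):
        rng = np.random.default_rng(4)
        a, b, c = (_exposure(rng.uniform(0, 100, (3, 4, 2, 2)))
                   for _ in range(3))
        direct = hx.impact_difference(a, c)
        chained = hx.impact_difference(a, b).values \
            + hx.impact_difference(b, c).values
        np.testing.assert_allclose(direct.values, chained, atol=1e-10)

    def test_member_count_mismatch_rejected(self):
        a = _exposure(np.zeros((3, 2, 2, 2)))
        b = _exposure(np.zeros((2, 2, 2, 2)))
        with pytest.raises(InputError):
            hx.impact_difference(a, b)


class TestAgreement:
    @pytest.mark.parametrize(
        "members, expected",
        [
            ((12.0, 15.0, 30.0), True),
            ((12.0, -15.0, 30.0), False),   # direction disagrees
            ((12.0, 15.0, 9.0), False),     # magnitude fails
            ((-12.0, -15.0, -30.0), True),
        ],
    )
    def test_hatching_rule(self, members, expected):
        impacts = xr.DataArray(
            np.array(members)[:, None, None], dims=("member", "lat", "lon"))
        assert bool(hx.agreement_mask(impacts)) is expected


class TestHotspots:
    @pytest.mark.parametrize(
        "hist, future, expected",
        [(0.25, 0.25, "traditional"), (0.05, 0.25, "new"),
         (0.05, 0.10, "none"), (0.20, 0.25, "new")],
    )
    def test_categories(self, hist, future, expected):
        h = xr.DataArray([[hist]], dims=("lat", "lon"))
        f = xr.DataArray([[future]], dims=("lat", "lon"))
        assert str(hx.classify_hotspots(h, f).item()) == expected

    def test_invalid_fraction_rejected(self):
        bad = xr.DataArray([[1.5]], dims=("lat", "lon"))
        with pytest.raises(InputError):
            hx.classify_hotspots(bad, bad)


class TestAggregation:
    def test_area_mean_uniform_and_weighted(self):
        field = xr.DataArray([[10.0, 30.0]], dims=("lat", "lon"))
        mask = xr.DataArray([[True, True]], dims=("lat", "lon"))
        equal = xr.DataArray([[1.0, 1.0]], dims=("lat", "lon"))
        skew = xr.DataArray([[1.0, 3.0]], dims=("lat", "lon"))
        assert float(hx.area_mean(field, mask, equal)) == pytest.approx(20.0)
        assert float(hx.area_mean(field, mask, skew)) == pytest.approx(25.0)

    def test_empty_mask_rejected(self):
        field = xr.DataArray([[1.0]], dims=("lat", "lon"))
        mask = xr.DataArray([[False]], dims=("lat", "lon"))
        with pytest.raises(EmptySelectionError):
            hx.area_mean(field, mask, xr.ones_like(field))

    def test_iww_unit_conversion(self):
        depth = xr.DataArray([[100.0]], dims=("lat", "lon"))
        area = xr.DataArray([[1000.0]], dims=("lat", "lon"))
        assert hx.aggregate_iww(depth, area) == pytest.approx(0.1)

    def test_iww_additivity_over_region_partition(self):
        rng = np.random.default_rng(5)
        depth = xr.DataArray(rng.uniform(0, 500, (4, 5)), dims=("lat", "lon"))
        area = xr.DataArray(rng.uniform(500, 2000, (4, 5)),
                            dims=("lat", "lon"))
        labels = xr.DataArray(rng.integers(0, 3, (4, 5)), dims=("lat", "lon"))
        total = hx.aggregate_iww(depth, area)
        parts = sum(hx.aggregate_iww(depth, area, labels == k)
                    for k in range(3))
        assert parts == pytest.approx(total, abs=1e-9)

    def test_negative_depth_rejected(self):
        depth = xr.DataArray([[-1.0]], dims=("lat", "lon"))
        with pytest.raises(InputError):
            hx.aggregate_iww(depth, xr.ones_like(depth))


class TestSavgol:
    def test_constant_series_unchanged(self):
        out = hx.savgol_smooth(np.full(20, 3.5))
        np.testing.assert_allclose(out, 3.5, atol=1e-12)

    def test_quadratic_reproduced_exactly(self):
        x = np.arange(30, dtype=float)
        y = 0.3 * x ** 2 - 2.0 * x + 1.0
        np.testing.assert_allclose(hx.savgol_smooth(y), y, atol=1e-9)

    def test_interior_matches_per_window_polyfit_oracle(self):
        rng = np.random.default_rng(6)
        y = np.sin(np.linspace(0, 6, 40)) + 0.1 * rng.normal(size=40)
        out = hx.savgol_smooth(y, order=2, window=7)
        half = 3
        for i in range(half, 40 - half):
            seg = y[i - half:i + half + 1]
            coeffs = np.polyfit(np.arange(-half, half + 1), seg, 2)
            assert out[i] == pytest.approx(coeffs[-1], abs=1e-9)

    @pytest.mark.parametrize("kwargs", [dict(window=6), dict(window=41),
                                        dict(order=9, window=7)])
    def test_bad_configuration_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            hx.savgol_smooth(np.zeros(40), **kwargs)
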