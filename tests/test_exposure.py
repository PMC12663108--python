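"""Exposure module: projection, grid lookup, dose weighting."""

import math
from datetime import date

import numpy as np
import pytest

from uvbgweis.exposure import (
    DailyDoseGrid,
    GridSpec,
    ResidenceRecord,
    WeightingParams,
    build_exposure_table,
    cumulative_weighted_dose,
    daily_series,
    decay_weights,
    latlon_to_cell,
    osgb_to_latlon,
    read_dose_grid,
    write_dose_grid,
)
from uvbgweis.simulate import UvbCalibration, simulate_uvb_grid

# ---------------------------------------------------------------------------
# forward transverse Mercator oracle (independent of the package inverse)
# ---------------------------------------------------------------------------

_A, _B = 6_377_563.396, 6_356_256.909
_F0, _PHI0, _LAM0 = 0.9996012717, math.radians(49.0), math.radians(-2.0)
_E0, _N0 = 400_000.0, -100_000.0


def forward_osgb(lat_deg, lon_deg):
    """Standard OSGB forward projection series (oracle)."""
    phi, lam = math.radians(lat_deg), math.radians(lon_deg)
    e2 = 1 - (_B / _A) ** 2
    n = (_A - _B) / (_A + _B)
    s, c, t = math.sin(phi), math.cos(phi), math.tan(phi)
    nu = _A * _F0 / math.sqrt(1 - e2 * s * s)
    rho = _A * _F0 * (1 - e2) * (1 - e2 * s * s) ** -1.5
    eta2 = nu / rho - 1
    m = _B * _F0 * (
        (1 + n + 1.25 * n**2 + 1.25 * n**3) * (phi - _PHI0)
        - (3 * n + 3 * n**2 + 2.625 * n**3)
        * math.sin(phi - _PHI0) * math.cos(phi + _PHI0)
        + (1.875 * n**2 + 1.875 * n**3)
        * math.sin(2 * (phi - _PHI0)) * math.cos(2 * (phi + _PHI0))
        - (35 / 24) * n**3
        * math.sin(3 * (phi - _PHI0)) * math.cos(3 * (phi + _PHI0))
    )
    i = m + _N0
    ii = nu / 2 * s * c
    iii = nu / 24 * s * c**3 * (5 - t**2 + 9 * eta2)
    iiia = nu / 720 * s * c**5 * (61 - 58 * t**2 + t**4)
    iv = nu * c
    v = nu / 6 * c**3 * (nu / rho - t**2)
    vi = nu / 120 * c**5 * (5 - 18 * t**2 + t**4 + 14 * eta2 - 58 * t**2 * eta2)
    dl = lam - _LAM0
    northing = i + ii * dl**2 + iii * dl**4 + iiia * dl**6
    easting = _E0 + iv * dl + v * dl**3 + vi * dl**5
    return easting, northing


class TestProjection:
    def test_true_origin_identity(self):
        lat, lon = osgb_to_latlon(400_000.0, -100_000.0)
        assert lat == pytest.approx(49.0, abs=1e-9)
        assert lon == pytest.approx(-2.0, abs=1e-9)

    @pytest.mark.parametrize("northing", [-100_000.0, 0.0, 250_000.0, 1_000_000.0])
    def test_central_meridian_longitude(self, northing):
        _, lon = osgb_to_latlon(400_000.0, northing)
        assert lon == pytest.approx(-2.0, abs=1e-12)

    def test_round_trip_against_forward_oracle(self, rng):
        lats = rng.uniform(50.0, 59.0, 100)
        lons = rng.uniform(-6.0, 1.5, 100)
        for lat, lon in zip(lats, lons):
            e, n = forward_osgb(lat, lon)
            lat2, lon2 = osgb_to_latlon(e, n)
            assert abs(lat2 - lat) < 1e-6
            assert abs(lon2 - lon) < 1e-6

    def test_out_of_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            osgb_to_latlon(5_000_000.0, 0.0)


class TestCellLookup:
    grid = GridSpec(lat_min=50.0, lon_min=-6.0, n_lat=8, n_lon=8)

    def test_cell_center_maps_to_cell(self):
        lat, lon = self.grid.cell_center(3, 5)
        assert latlon_to_cell(lat, lon, self.grid) == (3, 5)

    def test_interior_boundary_goes_to_higher_cell(self):
        # point exactly on the boundary between rows 2 and 3
        assert latlon_to_cell(50.75, -5.9, self.grid)[0] == 3

    def test_grid_origin_is_cell_zero(self):
        assert latlon_to_cell(50.0, -6.0, self.grid) == (0, 0)

    def test_outside_extent_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            latlon_to_cell(49.9, -5.0, self.grid)


def _constant_grid(value=1.0, n_days=200, start=date(2008, 1, 1)):
    grid = GridSpec(lat_min=50.0, lon_min=-6.0, n_lat=2, n_lon=2)
    dose = np.full((n_days, 2, 2), value)
    return DailyDoseGrid(grid=grid, start_date=start, dose=dose)


class TestDailySeries:
    params = WeightingParams()

    def test_fully_observed_window(self):
        gd = _constant_grid()
        series, n_obs, n_imp = daily_series(
            gd, (0, 0), date(2008, 6, 1), self.params
        )
        assert len(series) == 135 and n_obs == 135 and n_imp == 0

    def test_interior_gap_linearly_interpolated(self):
        gd = _constant_grid()
        d = gd.day_index(date(2008, 4, 1))
        gd.dose[d, 0, 0] = np.nan
        gd.dose[d - 1, 0, 0] = 2.0
        gd.dose[d + 1, 0, 0] = 4.0
        series, n_obs, n_imp = daily_series(
            gd, (0, 0), date(2008, 6, 1), self.params
        )
        assert n_imp == 1 and n_obs == 134
        lag = (date(2008, 6, 1) - date(2008, 4, 1)).days
        assert series[lag - 1] == pytest.approx(3.0)

    def test_window_before_grid_start_is_error(self):
        gd = _constant_grid()
        with pytest.raises(ValueError, match="coverage"):
            daily_series(gd, (0, 0), date(2008, 2, 1), self.params)

    def test_too_many_missing_days_is_error(self):
        gd = _constant_grid()
        i0 = gd.day_index(date(2008, 3, 1))
        gd.dose[i0 : i0 + 20, 0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            daily_series(gd, (0, 0), date(2008, 6, 1), self.params)


class TestWeightedDose:
    params = WeightingParams()

    def test_zero_series(self):
        assert cumulative_weighted_dose(np.zeros(135), self.params) == 0.0

    def test_single_dose_at_half_life_lag_halves(self):
        series = np.zeros(135)
        series[34] = 7.0  # lag x = 35
        assert cumulative_weighted_dose(series, self.params) == pytest.approx(
            3.5, rel=1e-12
        )

    def test_constant_series_geometric_closed_form(self):
        r = math.exp(-math.log(2) / 35)
        expected = r * (1 - r**135) / (1 - r)
        got = cumulative_weighted_dose(np.ones(135), self.params)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_weight_halving_and_monotone_decay(self):
        w = decay_weights(self.params)
        assert np.all(np.diff(w) < 0)
        assert np.allclose(w[35:], w[:-35] / 2, rtol=1e-12)

    def test_homogeneity_and_additivity(self, rng):
        s1 = rng.gamma(2.0, 1.0, 135)
        s2 = rng.gamma(2.0, 1.0, 135)
        f = lambda s: cumulative_weighted_dose(s, self.params)
        assert f(3.0 * s1) == pytest.approx(3.0 * f(s1), rel=1e-12)
        assert f(s1 + s2) == pytest.approx(f(s1) + f(s2), rel=1e-12)

    def test_negative_dose_rejected(self):
        bad = np.ones(135)
        bad[5] = -0.1
        with pytest.raises(ValueError, match="non-negative"):
            cumulative_weighted_dose(bad, self.params)


class TestExposureTable:
    def test_translation_invariance_on_constant_grid(self):
        gd = _constant_grid(value=2.0, n_days=300)
        recs = [
            ResidenceRecord("a", date(2008, 6, 1), lat_deg=50.1, lon_deg=-5.9),
            ResidenceRecord("b", date(2008, 7, 6), lat_deg=50.1, lon_deg=-5.9),
        ]
        table, failures = build_exposure_table(recs, gd)
        assert not failures
        assert table["cwduvb"].iloc[0] == pytest.approx(table["cwduvb"].iloc[1])

    def test_linearity_in_dose(self):
        gd1 = _constant_grid(value=1.0)
        gd3 = _constant_grid(value=3.0)
        rec = [ResidenceRecord("a", date(2008, 6, 1), lat_deg=50.1, lon_deg=-5.9)]
        t1, _ = build_exposure_table(rec, gd1)
        t3, _ = build_exposure_table(rec, gd3)
        assert t3["cwduvb"].iloc[0] == pytest.approx(3 * t1["cwduvb"].iloc[0])

    def test_winter_below_summer_on_seasonal_grid(self):
        grid = GridSpec(lat_min=51.0, lon_min=-1.0, n_lat=2, n_lon=2)
        gd = simulate_uvb_grid(grid, date(2008, 1, 1), 365, seed=3,
                               cloud_noise=False)
        recs = [
            ResidenceRecord("winter", date(2008, 12, 15), lat_deg=51.2, lon_deg=-0.8),
            ResidenceRecord("summer", date(2008, 8, 1), lat_deg=51.2, lon_deg=-0.8),
        ]
        table, failures = build_exposure_table(recs, gd)
        assert not failures
        tab = table.set_index("participant_id")["cwduvb"]
        assert tab["winter"] < tab["summer"]

    def test_osgb_and_latlon_inputs_agree(self):
        gd = _constant_grid(value=1.5, n_days=300)
        lat, lon = 50.3, -5.6
        e, n = forward_osgb(lat, lon)
        recs = [
            ResidenceRecord("ll", date(2008, 6, 1), lat_deg=lat, lon_deg=lon),
            ResidenceRecord("en", date(2008, 6, 1), easting_m=e, northing_m=n),
        ]
        table, failures = build_exposure_table(recs, gd)
        assert not failures
        vals = table.set_index("participant_id")["cwduvb"]
        assert vals["ll"] == pytest.approx(vals["en"], rel=1e-12)

    def test_unresolvable_residence_collected_not_fatal(self):
        gd = _constant_grid()
        recs = [
            ResidenceRecord("bad", date(2008, 6, 1), lat_deg=10.0, lon_deg=10.0),
            ResidenceRecord("good", date(2008, 6, 1), lat_deg=50.1, lon_deg=-5.9),
        ]
        table, failures = build_exposure_table(recs, gd)
        assert [pid for pid, _ in failures] == ["bad"]
        assert list(table["participant_id"]) == ["good"]

    def test_record_requires_exactly_one_coordinate_form(self):
        with pytest.raises(ValueError, match="exactly one"):
            ResidenceRecord("x", date(2008, 6, 1))


def test_dose_grid_roundtrip(tmp_path):
    grid = GridSpec(lat_min=51.0, lon_min=-1.0, n_lat=2, n_lon=3)
    gd = simulate_uvb_grid(grid, date(2008, 1, 1), 40, seed=5)
    gd.dose[3, 0, 1] = np.nan
    path = tmp_path / "grid.tsv"
    write_dose_grid(path, gd)
    back = read_dose_grid(path)
    assert back.grid == grid
    assert back.start_date == gd.start_date
    np.testing.assert_allclose(back.dose, gd.dose, rtol=1e-4, equal_nan=True)
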