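import math

import numpy as np
import pandas as pd
import pytest

from sealdive import hydro as H
from sealdive.errors import DataError
from sealdive.geo import haversine_km
from .conftest import make_cast, random_casts


# ---------------------------------------------------------------------------
# Equation of state: published check values
# ---------------------------------------------------------------------------


def test_density_unesco_check_values():
    # UNESCO (1983) standard check values for the EOS-80 density algorithm
    assert H.density_eos80(0.0, 5.0, 0.0) == pytest.approx(999.96675, abs=1e-5)
    assert H.density_eos80(35.0, 5.0, 0.0) == pytest.approx(1027.67547, abs=1e-5)
    assert H.density_eos80(35.0, 25.0, 10_000.0) == pytest.approx(1062.53817, abs=1e-5)
    assert H.density_eos80(35.0, 25.0, 0.0) == pytest.approx(1023.34306, abs=1e-5)


def test_potential_temperature_fofonoff_check_value():
    # Fofonoff & Millard (1983) check value
    assert H.potential_temperature(40.0, 40.0, 10_000.0, 0.0) == pytest.approx(
        36.89073, abs=1e-5)


def test_potential_density_surface_reference():
    # at the surface, sigma-theta is just in-situ density minus 1000
    s, t = 34.3, 4.0
    assert H.potential_density(s, t, 0.0) == pytest.approx(
        H.density_eos80(s, t, 0.0) - 1000.0, abs=1e-9)
    # referencing to the surface removes (nearly all of) the pressure effect;
    # the tiny residual is the adiabatic cooling over 100 dbar
    assert H.potential_density(s, t, 100.0) == pytest.approx(
        H.potential_density(s, t, 0.0), abs=2e-3)


def test_potential_density_range_check():
    with pytest.raises(DataError, match="outside valid range"):
        H.potential_density(50.0, 4.0)
    with pytest.raises(DataError):
        H.potential_density(34.0, -3.0)


def test_pressure_from_depth():
    assert H.pressure_from_depth(100.0) == 100.0
    # Saunders (1981): pressure slightly exceeds depth at high latitude
    p = H.pressure_from_depth(1000.0, lat=78.0)
    assert 1000.0 < p < 1020.0


# ---------------------------------------------------------------------------
# Mixed-layer depth
# ---------------------------------------------------------------------------


def test_mld_linear_ramp_closed_form():
    # constant sigma above 30 m, then a linear-in-depth salinity ramp; the
    # expected MLD is the exact linear crossing computed here from the sigma
    # values by plain interpolation arithmetic, independent of the estimator
    z = np.arange(3.0, 83.0, 5.0)
    sal = np.where(z <= 30.0, 34.3, 34.3 + 0.002 * (z - 30.0))
    cast = make_cast(depths=z, temps=np.full(len(z), 4.0), sals=sal)
    sigma = H.potential_density(sal, np.full(len(z), 4.0),
                                H.pressure_from_depth(z))
    sigma_ref = np.interp(6.0, z, sigma)
    thr = sigma_ref + 0.03
    i = int(np.argmax(sigma >= thr))
    expected = z[i - 1] + (thr - sigma[i - 1]) / (sigma[i] - sigma[i - 1]) \
        * (z[i] - z[i - 1])
    est = H.mixed_layer_depth(cast)
    assert est.valid and not est.bottom_limited
    assert est.mld_m == pytest.approx(expected, abs=1e-6)


def test_mld_bottom_limited_flag():
    # perfectly mixed cast: threshold never exceeded
    cast = make_cast(depths=np.arange(3.0, 60.0, 5.0))
    est = H.mixed_layer_depth(cast)
    assert est.valid and est.bottom_limited
    assert est.mld_m == pytest.approx(58.0)


def test_mld_invalid_when_cast_too_shallow():
    cast = make_cast(depths=np.array([2.0, 4.0]), temps=np.array([4.0, 4.0]),
                     sals=np.array([34.3, 34.3]))
    est = H.mixed_layer_depth(cast)
    assert not est.valid and math.isnan(est.mld_m)


def test_mld_table_columns():
    tab = H.mld_table([make_cast(), make_cast(cast_id="C2")])
    assert list(tab["cast_id"]) == ["C1", "C2"]
    assert {"mld_m", "valid", "bottom_limited", "lon", "lat", "time"} <= set(tab.columns)


def test_cast_requires_increasing_depths():
    with pytest.raises(DataError, match="strictly increasing"):
        make_cast(depths=np.array([5.0, 10.0, 10.0]),
                  temps=np.zeros(3) + 4, sals=np.zeros(3) + 34)


# ---------------------------------------------------------------------------
# Gaussian-weighted T/S assignment: double-loop oracle
# ---------------------------------------------------------------------------


def oracle_interpolate_ts(time, lon, lat, depth, casts):
    """Literal double loop over casts and levels with scalar arithmetic."""
    t_target = pd.Timestamp(time).value / 1e9
    wsum = wT = wS = 0.0
    for c in casts:
        for k in range(len(c.depth_m)):
            dt = (c.time.value / 1e9 - t_target) / 86_400.0
            dxy = float(haversine_km(lon, lat, c.lon, c.lat))
            dz = c.depth_m[k] - depth
            w = math.exp(-0.5 * (dt / 3.0) ** 2) \
                * math.exp(-0.5 * (dxy / 25.0) ** 2) \
                * math.exp(-0.5 * (dz / 5.0) ** 2)
            wsum += w
            wT += w * c.temp_c[k]
            wS += w * c.sal_psu[k]
    return wT / wsum, wS / wsum, wsum


def test_interpolate_ts_matches_double_loop(rng):
    casts = random_casts(rng, n=50)
    targets = [(pd.Timestamp("2010-10-05T12:00:00Z"), 13.0, 78.2, 40.0),
               (pd.Timestamp("2010-10-01T00:00:00Z"), 12.7, 78.15, 6.0),
               (pd.Timestamp("2010-10-12T18:00:00Z"), 13.3, 78.3, 120.0)]
    for time, lon, lat, depth in targets:
        T, S, w, n = H.interpolate_ts(time, lon, lat, depth, casts)
        T0, S0, w0 = oracle_interpolate_ts(time, lon, lat, depth, casts)
        assert T == pytest.approx(T0, abs=1e-9)
        assert S == pytest.approx(S0, abs=1e-9)
        assert w == pytest.approx(w0, rel=1e-9)
        assert n > 0


def test_interpolate_ts_below_floor_returns_nan(rng):
    casts = random_casts(rng, n=5)
    T, S, w, n = H.interpolate_ts(pd.Timestamp("2012-01-01T00:00:00Z"),
                                  0.0, 0.0, 40.0, casts)
    assert math.isnan(T) and math.isnan(S) and n == 0


def test_assign_hydrography_flags(rng):
    casts = random_casts(rng, n=20)
    dives = pd.DataFrame({
        "start": pd.to_datetime(["2010-10-05T06:00:00Z", "2012-06-01T00:00:00Z"]),
        "lon": [13.0, 0.0], "lat": [78.2, 0.0], "max_depth_m": [50.0, 50.0]})
    out = H.assign_hydrography(dives, casts)
    assert bool(out["hydro_reliable"].iloc[0])
    assert not bool(out["hydro_reliable"].iloc[1])
    assert np.isfinite(out["T_surface"].iloc[0])


# ---------------------------------------------------------------------------
# Regions, series, water masses
# ---------------------------------------------------------------------------


def test_assign_region_half_open():
    box = H.RegionBox("shelf", 12.0, 13.0, 78.0, 78.5)
    assert H.assign_region(12.0, 78.0, [box]) == "shelf"
    assert H.assign_region(13.0, 78.2, [box]) is None
    assert H.assign_region(12.5, 78.5, [box]) is None


def test_region_series_interpolates_and_gaps(rng):
    box = H.RegionBox("all", 0.0, 360.0, 0.0, 90.0)
    casts = [make_cast(cast_id="C1", time="2010-10-01T12:00:00Z",
                       depths=np.array([3.0, 50.0, 100.0]),
                       temps=np.array([5.0, 4.0, 3.0]),
                       sals=np.array([34.0, 34.2, 34.4])),
             make_cast(cast_id="C2", time="2010-10-10T12:00:00Z",
                       depths=np.array([3.0, 50.0, 100.0]),
                       temps=np.array([5.0, 4.5, 3.5]),
                       sals=np.array([34.0, 34.2, 34.4]))]
    out = H.region_series(casts, [box], var="temp_c", depth_levels=(50.0,))
    on_day = out[(out["date"] == "2010-10-01") & (out["depth_m"] == 50.0)]
    assert on_day["temp_c"].iloc[0] == pytest.approx(4.0, abs=1e-9)
    mid = out[(out["date"] == "2010-10-05") & (out["depth_m"] == 50.0)]
    assert math.isnan(mid["temp_c"].iloc[0])    # gap, never filled with zeros


def test_water_mass_labels():
    assert H.water_mass_label(4.0, 34.95) == "AW"
    assert H.water_mass_label(0.5, 34.3) == "ArW"
    assert H.water_mass_label(2.0, 34.8) == "mixed"
    assert H.water_mass_label(4.0, 34.5) == "mixed"   # warm but fresh
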