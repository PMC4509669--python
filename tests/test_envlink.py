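import numpy as np
import pandas as pd
import pytest

from sealdive import envlink as E
from sealdive.errors import DataError


# ---------------------------------------------------------------------------
# Divergence series
# ---------------------------------------------------------------------------


def _daily(dates, col, vals):
    return pd.DataFrame({"date": pd.to_datetime(dates), col: vals})


def test_divergence_series_union_and_gaps():
    depth = _daily(["2010-10-01", "2010-10-02", "2010-10-04"],
                   "mean_dive_depth", [40.0, 42.0, 41.0])
    mld = _daily(["2010-10-02", "2010-10-03", "2010-10-05"],
                 "mld", [60.0, 61.0, 63.0])
    out = E.divergence_series(depth, mld)
    assert len(out) == 5                               # full daily range
    byday = out.set_index("date")
    assert byday.loc["2010-10-02", "diff"] == pytest.approx(18.0)
    assert np.isnan(byday.loc["2010-10-01", "diff"])   # mld missing: gap
    assert np.isnan(byday.loc["2010-10-03", "diff"])   # depth missing: gap
    assert np.isnan(byday.loc["2010-10-04", "diff"])


def test_divergence_series_requires_overlap():
    depth = _daily(["2010-10-01"], "mean_dive_depth", [40.0])
    mld = _daily(["2010-11-01"], "mld", [60.0])
    with pytest.raises(DataError, match="no overlapping dates"):
        E.divergence_series(depth, mld)


def test_divergence_smooth_is_presentation_only():
    n = 30
    depth = _daily(pd.date_range("2010-10-01", periods=n), "mean_dive_depth",
                   np.linspace(40, 50, n))
    mld = _daily(pd.date_range("2010-10-01", periods=n), "mld",
                 np.linspace(60, 90, n))
    out = E.divergence_series(depth, mld)
    assert "diff_smooth" in out.columns
    # raw diff is untouched by the smoothing
    np.testing.assert_allclose(out["diff"], np.linspace(20, 40, n))


# ---------------------------------------------------------------------------
# Change point: exhaustive-search oracle
# ---------------------------------------------------------------------------


def oracle_change_point(y, min_segment=2):
    """Direct exhaustive evaluation of the mean-shift likelihood ratio."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    best_stat, best_tau = -np.inf, None
    for tau in range(min_segment, n - min_segment + 1):
        a, b = y[:tau], y[tau:]
        rss = float(np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
        stat = n * np.log(rss0 / rss) if rss > 0 else np.inf
        if stat > best_stat:
            best_stat, best_tau = stat, tau
    return best_tau, best_stat


def test_change_point_matches_exhaustive_oracle(rng):
    n = 500
    y = rng.normal(0, 5, n)
    y[320:] += 12.0
    dates = pd.date_range("2010-06-01", periods=n, freq="D")
    res = E.change_point(pd.DataFrame({"date": dates, "diff": y}))
    tau0, stat0 = oracle_change_point(y)
    assert res.change_index == tau0
    assert res.statistic == pytest.approx(stat0, rel=1e-12)
    assert res.change_date == dates[tau0]
    assert res.significant
    assert res.post_mean - res.pre_mean == pytest.approx(12.0, abs=1.5)


def test_change_point_oracle_on_pure_noise(rng):
    y = rng.normal(0, 1, 500)
    res = E.change_point(pd.Series(y, index=pd.date_range("2010-01-01", periods=500)))
    tau0, stat0 = oracle_change_point(y)
    assert res.change_index == tau0
    assert res.statistic == pytest.approx(stat0, rel=1e-12)


def test_change_point_insignificant_on_flat_series():
    # tiny deterministic wiggle: statistic cannot beat the 3 log n penalty
    y = np.tile([0.0, 0.1], 25)
    res = E.change_point(pd.Series(y, index=pd.date_range("2010-01-01", periods=50)))
    assert not res.significant


def test_change_point_nan_days_dropped(rng):
    y = rng.normal(0, 2, 60)
    y[40:] += 10.0
    dates = pd.date_range("2010-06-01", periods=60, freq="D")
    df = pd.DataFrame({"date": dates, "diff": y})
    df.loc[5, "diff"] = np.nan
    res = E.change_point(df)
    assert res.change_date == dates[40]


def test_change_point_too_short_raises():
    with pytest.raises(DataError, match="too short"):
        E.change_point(pd.Series(np.arange(10.0),
                                 index=pd.date_range("2010-01-01", periods=10)))


# ---------------------------------------------------------------------------
# Wind covariates
# ---------------------------------------------------------------------------


def _wind(times, u, v):
    return pd.DataFrame({"time": times, "u": u, "v": v})


def test_wind_from_bearing_conventions():
    # blowing toward the south means coming from the north: bearing 0
    assert E.wind_from_bearing(0.0, -5.0) == pytest.approx(0.0)
    assert E.wind_from_bearing(-5.0, 0.0) == pytest.approx(90.0)   # from east
    assert E.wind_from_bearing(0.0, -5.0, from_convention=True) == pytest.approx(180.0)


def test_wind_covariates_sector_and_mean():
    times = pd.date_range("2010-10-01", periods=8, freq="6h", tz="UTC")
    # first day: from-north records of speed 10; second day: from-south
    u = np.zeros(8)
    v = np.concatenate([np.full(4, -10.0), np.full(4, 10.0)])
    wind = _wind(times, u, v)
    cov = E.wind_covariates(wind, ["2010-10-02", "2010-10-03"], lag_days=1,
                            sector="N")
    assert cov["value"].iloc[0] == pytest.approx(10.0)
    assert cov["value"].iloc[1] == 0.0                  # no qualifying record
    assert cov["n_records"].iloc[1] == 0
    assert not bool(cov["flagged"].iloc[0])


def test_wind_covariates_stress_conversion():
    times = pd.date_range("2010-10-01", periods=4, freq="6h", tz="UTC")
    wind = _wind(times, np.zeros(4), np.full(4, -8.0))
    cov = E.wind_covariates(wind, ["2010-10-02"], lag_days=1, sector="N",
                            as_stress=True)
    assert cov["value"].iloc[0] == pytest.approx(E.RHO_AIR * E.DRAG_COEFF * 64.0)


def test_wind_covariates_shift_equivariance(rng):
    times = pd.date_range("2010-10-01", periods=40, freq="6h", tz="UTC")
    u = rng.normal(0, 5, 40)
    v = rng.normal(0, 5, 40)
    dates = ["2010-10-05", "2010-10-08"]
    base = E.wind_covariates(_wind(times, u, v), dates, lag_days=3, sector="NE")
    shift = pd.Timedelta(days=11)
    moved = E.wind_covariates(_wind(times + shift, u, v),
                              [pd.Timestamp(d) + shift for d in dates],
                              lag_days=3, sector="NE")
    np.testing.assert_allclose(moved["value"], base["value"])
    assert moved["n_records"].tolist() == base["n_records"].tolist()


def test_wind_covariates_window_is_half_open():
    times = pd.date_range("2010-10-01", periods=9, freq="6h", tz="UTC")
    u = np.zeros(9)
    v = np.full(9, -10.0)
    v[4] = -20.0    # midnight record of Oct 2: excluded from Oct 2's [d-1, d) window
    cov = E.wind_covariates(_wind(times, u, v), ["2010-10-02"], lag_days=1,
                            sector="N")
    assert cov["value"].iloc[0] == pytest.approx(10.0)


def test_wind_covariates_flags_sparse_window():
    times = pd.date_range("2010-10-01", periods=20, freq="6h", tz="UTC")
    wind = _wind(times, np.zeros(20), np.full(20, -5.0))
    cov = E.wind_covariates(wind, ["2010-10-20"], lag_days=7, sector="N")
    assert bool(cov["flagged"].iloc[0])     # window mostly before the series


def test_wind_covariates_lag_validation():
    wind = _wind(pd.date_range("2010-10-01", periods=4, freq="6h", tz="UTC"),
                 np.zeros(4), np.zeros(4))
    with pytest.raises(DataError, match="lag"):
        E.wind_covariates(wind, ["2010-10-02"], lag_days=0)
    with pytest.raises(DataError, match="sector"):
        E.wind_covariates(wind, ["2010-10-02"], lag_days=1, sector="SW")
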