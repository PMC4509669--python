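import numpy as np
import pandas as pd
import pytest

from sealdive import dives as D
from sealdive.errors import DataError
from sealdive.geo import LocalPlane
from sealdive.io import OUTSIDE_DOMAIN, RasterGrid
from sealdive.tracks import TrackModel, fit_track
from .conftest import make_track_frame


# ---------------------------------------------------------------------------
# Bottom time (closed forms)
# ---------------------------------------------------------------------------


def test_v_dive_bottom_time_is_one_fifth_duration():
    # symmetric V profile: constant descent to D at T/2, constant ascent back.
    # Time deeper than 0.8 D is the top 20 % of each leg: exactly 0.2 T.
    T, depth = 600.0, 100.0
    t = np.array([0.25, 0.5, 0.625, 0.75]) * T
    d = np.array([0.5, 1.0, 0.75, 0.5]) * depth
    bt = D.bottom_time(T, depth, t, d)
    assert bt == pytest.approx(0.2 * T, abs=1e-6)


def test_square_dive_bottom_time():
    # flat-bottom profile: at depth D from t1 to t4, so bottom time is
    # t4 - t1 plus the 20 % tails of the two travel legs
    T, depth = 500.0, 80.0
    t1, t4 = 100.0, 400.0
    bt = D.bottom_time(T, depth, [t1, 200.0, 300.0, t4],
                       [depth, depth, depth, depth])
    assert bt == pytest.approx((t4 - t1) + 0.2 * t1 + 0.2 * (T - t4), abs=1e-6)


def test_touching_threshold_has_zero_measure():
    # profile touches exactly 0.8 D at one instant and returns: no bottom time
    T, depth = 100.0, 50.0
    bt = D.bottom_time(T, depth, [20.0, 40.0, 60.0, 80.0],
                       [10.0, 0.8 * depth, 10.0, 5.0])
    assert bt == 0.0


def test_profile_rejects_nonmonotone_offsets():
    with pytest.raises(DataError, match="increase strictly"):
        D.profile_points(100.0, [10.0, 50.0, 40.0, 90.0], [1, 2, 3, 4])
    with pytest.raises(DataError):
        D.profile_points(100.0, [10.0, 50.0, 60.0, 100.0], [1, 2, 3, 4])


def test_bottom_time_table_matches_scalar():
    df = pd.DataFrame({
        "animal_id": ["A", "A"], "duration_s": [600.0, 500.0],
        "max_depth_m": [100.0, 80.0],
        "t1": [150.0, 100.0], "t2": [300.0, 200.0],
        "t3": [375.0, 300.0], "t4": [450.0, 400.0],
        "d1": [50.0, 80.0], "d2": [100.0, 80.0],
        "d3": [75.0, 80.0], "d4": [50.0, 80.0]})
    tab = D.bottom_time_table(df)
    for i in range(len(df)):
        row = df.iloc[i]
        assert tab.iloc[i] == pytest.approx(D.bottom_time(
            row["duration_s"], row["max_depth_m"],
            row[["t1", "t2", "t3", "t4"]].to_numpy(float),
            row[["d1", "d2", "d3", "d4"]].to_numpy(float)))


# ---------------------------------------------------------------------------
# Daily series
# ---------------------------------------------------------------------------


def _summaries(animal="A", day="2010-07-01", hours=(0, 6, 12, 18)):
    rows = []
    for h in hours:
        rows.append({"animal_id": animal,
                     "period_start": pd.Timestamp(f"{day}T{h:02d}:00:00", tz="UTC"),
                     "avg_depth_m": 30.0 + h, "avg_duration_s": 200.0,
                     "n_dives": 10, "time_diving_s": 2000.0,
                     "surface_time_s": 19600.0})
    return pd.DataFrame(rows)


def test_daily_series_completeness_flag():
    full = _summaries()
    partial = _summaries(day="2010-07-02", hours=(0, 6, 12))
    out = D.daily_series(pd.concat([full, partial], ignore_index=True))
    assert bool(out.loc[out["date"].dt.day == 1, "complete"].iloc[0])
    assert not bool(out.loc[out["date"].dt.day == 2, "complete"].iloc[0])
    row = out[out["date"].dt.day == 1].iloc[0]
    assert row["depth_m"] == pytest.approx(np.mean([30, 36, 42, 48]))
    assert row["n_dives"] == 40
    assert row["dive_surface_ratio"] == pytest.approx(8000.0 / 78400.0)


def test_daily_series_duplicate_period_raises():
    df = pd.concat([_summaries(), _summaries().iloc[[0]]], ignore_index=True)
    with pytest.raises(DataError, match="duplicate"):
        D.daily_series(df)


# ---------------------------------------------------------------------------
# Effort residuals
# ---------------------------------------------------------------------------


def _dive_table(rng, animal="A", n=200):
    depth = rng.uniform(20, 120, n)
    t_desc = depth / 1.2
    dur = 2.5 * t_desc + rng.normal(0, 20, n) + 60
    bt = 0.4 * dur + 0.5 * depth + rng.normal(0, 15, n)
    return pd.DataFrame({"animal_id": animal, "duration_s": dur,
                         "max_depth_m": depth, "bottom_time_s": bt})


def test_effort_residuals_standardized(rng):
    df = pd.concat([_dive_table(rng, "A"), _dive_table(rng, "B")],
                   ignore_index=True)
    out = D.effort_residuals(df)
    for _, grp in out.groupby("animal_id"):
        assert abs(grp["effort_residual"].mean()) < 1e-6
        assert grp["effort_residual"].std(ddof=0) == pytest.approx(1.0, abs=1e-6)


def test_effort_residuals_skips_small_animals(rng):
    df = pd.concat([_dive_table(rng, "A"), _dive_table(rng, "B", n=5)],
                   ignore_index=True)
    with pytest.warns(UserWarning, match="skipped"):
        out = D.effort_residuals(df)
    assert set(out["animal_id"]) == {"A"}


def test_effort_residuals_rank_deficient_raises():
    df = pd.DataFrame({"animal_id": "A", "duration_s": 100.0,
                       "max_depth_m": 50.0,
                       "bottom_time_s": np.arange(20.0)})
    with pytest.raises(DataError, match="rank-deficient"):
        D.effort_residuals(df)


# ---------------------------------------------------------------------------
# Classification and diel bins
# ---------------------------------------------------------------------------


def test_classify_dive_rules():
    assert D.classify_dive(30.0, 45.0) == "coastal"       # bathy < 50 m
    assert D.classify_dive(96.0, 100.0) == "benthic"      # ratio 0.96
    assert D.classify_dive(95.0, 100.0) == "pelagic"      # ratio exactly 0.95
    assert D.classify_dive(40.0, 100.0) == "pelagic"
    assert D.classify_dive(40.0, OUTSIDE_DOMAIN) == "unclassified"
    assert D.classify_dive(40.0, np.nan) == "unclassified"
    assert D.classify_dive(40.0, -5.0) == "unclassified"


def test_classify_dives_against_raster():
    grid = RasterGrid(values=np.array([[45.0, 100.0]]), x_ll=10.0, y_ll=78.0,
                      cellsize=1.0)
    df = pd.DataFrame({"lon": [10.5, 11.5, 13.5], "lat": [78.5] * 3,
                       "max_depth_m": [30.0, 99.0, 40.0]})
    labels = D.classify_dives(df, grid)
    assert labels.tolist() == ["coastal", "benthic", "unclassified"]


def test_diel_bins():
    assert D.diel_bin("2010-10-01T05:59:00") == "night_am"
    assert D.diel_bin("2010-10-01T06:00:00") == "day"
    assert D.diel_bin("2010-10-01T17:59:00") == "day"
    assert D.diel_bin("2010-10-01T18:00:00") == "night_pm"
    assert D.diel_period("2010-10-01T02:00:00") == "night"
    assert D.diel_period("2010-10-01T12:00:00") == "day"


# ---------------------------------------------------------------------------
# Time spent in area
# ---------------------------------------------------------------------------


def test_allocate_segment_exact_split():
    cells = {}
    # 2 km horizontal segment crossing one 1-km cell line at x=1, 300 s
    D._allocate_segment(cells, 0.5, 0.5, 2.5, 0.5, 300.0, 1.0)
    assert cells[(0, 0)] == pytest.approx(300.0 * 0.25)
    assert cells[(1, 0)] == pytest.approx(300.0 * 0.5)
    assert cells[(2, 0)] == pytest.approx(300.0 * 0.25)
    assert sum(cells.values()) == pytest.approx(300.0)


def _fitted_model(rng, plane, n=100):
    obs = make_track_frame(rng, plane, n=n, walk_sd_km=0.4)
    return fit_track(obs, fit_error_scale=False, class_sd_km={"3": 0.3})


def test_tsa_conserves_time(rng, plane):
    model = _fitted_model(rng, plane)
    tsa = D.compute_tsa(model, cell_km=5.0, step_minutes=10.0)
    span = model.span[1] - model.span[0]
    assert tsa.total_seconds == pytest.approx(span, rel=1e-3)


def test_tsa_conserves_time_with_haulouts(rng, plane):
    model = _fitted_model(rng, plane)
    t0, t1 = model.span
    model.haulouts_s = [(t0 + 3600.0, t0 + 3 * 3600.0)]
    tsa = D.compute_tsa(model, cell_km=5.0, step_minutes=10.0)
    assert tsa.total_seconds == pytest.approx((t1 - t0) - 7200.0, rel=1e-3)


def test_tsa_high_usage_is_top_quartile(rng, plane):
    model = _fitted_model(rng, plane, n=200)
    tsa = D.compute_tsa(model, cell_km=2.0)
    positive = {k: v for k, v in tsa.cells.items() if v > 0}
    assert 0 < len(tsa.high_usage) <= np.ceil(0.25 * len(positive))
    worst_marked = min(positive[k] for k in tsa.high_usage)
    best_unmarked = max((v for k, v in positive.items()
                         if k not in tsa.high_usage), default=-np.inf)
    assert worst_marked >= best_unmarked


def test_high_usage_dives_mask(rng, plane):
    model = _fitted_model(rng, plane)
    tsa = D.compute_tsa(model, cell_km=2.0)
    key = next(iter(tsa.high_usage))
    x = (key[0] + 0.5) * tsa.cell_km
    y = (key[1] + 0.5) * tsa.cell_km
    lon, lat = plane.to_lonlat(np.array([x]), np.array([y]))
    far_lon, far_lat = plane.to_lonlat(np.array([900.0]), np.array([900.0]))
    df = pd.DataFrame({"lon": [lon[0], far_lon[0]], "lat": [lat[0], far_lat[0]]})
    mask = D.high_usage_dives(df, tsa, plane)
    assert mask.tolist() == [True, False]
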