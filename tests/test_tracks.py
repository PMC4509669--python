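import numpy as np
import pandas as pd
import pytest

from sealdive.errors import DataError
from sealdive.geo import LocalPlane, haversine_km, turning_angle_deg
from sealdive.tracks import (VMAX_MS, SPIKE_RULES, TrackModel, detect_haulouts,
                             fit_track, locate, sda_filter)
from .conftest import make_track_frame


# ---------------------------------------------------------------------------
# SDA filter: brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_sda(grp: pd.DataFrame, vmax_ms=VMAX_MS, rules=SPIKE_RULES):
    """Independent, deliberately naive re-statement of the filter rule.

    Scan all interior points each pass with per-point arithmetic; remove the
    worst both-neighbour speed violator, else the sharpest rule-matching
    spike; repeat to fixpoint.  Returns the surviving row positions.
    """
    grp = grp.sort_values("time").reset_index(drop=True)
    t = grp["time"].astype("int64").to_numpy() / 1e9
    lon = grp["lon"].to_numpy()
    lat = grp["lat"].to_numpy()
    alive = list(range(len(grp)))
    while len(alive) >= 3:
        def speed(i, j):
            dt = t[alive[j]] - t[alive[i]]
            d = haversine_km(lon[alive[i]], lat[alive[i]],
                             lon[alive[j]], lat[alive[j]])
            return d * 1000.0 / dt if dt > 0 else np.inf

        best = None
        for k in range(1, len(alive) - 1):
            s1, s2 = speed(k - 1, k), speed(k, k + 1)
            if s1 > vmax_ms and s2 > vmax_ms:
                worst = max(s1, s2)
                if best is None or worst > best[0]:
                    best = (worst, k)
        if best is not None:
            alive.pop(best[1])
            continue
        best = None
        for k in range(1, len(alive) - 1):
            ang = turning_angle_deg(lon[alive[k - 1]], lat[alive[k - 1]],
                                    lon[alive[k]], lat[alive[k]],
                                    lon[alive[k + 1]], lat[alive[k + 1]])
            l1 = haversine_km(lon[alive[k - 1]], lat[alive[k - 1]],
                              lon[alive[k]], lat[alive[k]])
            l2 = haversine_km(lon[alive[k]], lat[alive[k]],
                              lon[alive[k + 1]], lat[alive[k + 1]])
            if any(ang < amax and l1 > lmin and l2 > lmin for amax, lmin in rules):
                if best is None or ang < best[0]:
                    best = (ang, k)
        if best is None:
            break
        alive.pop(best[1])
    return grp.loc[alive]


def _noisy_track(rng, plane, n=200):
    """Random walk with injected speed outliers and spikes."""
    df = make_track_frame(rng, plane, n=n, walk_sd_km=0.8)
    x, y = plane.to_xy(df["lon"].to_numpy(), df["lat"].to_numpy())
    # big displacement outliers at random interior points
    for k in rng.choice(np.arange(2, n - 2), size=12, replace=False):
        x[k] += rng.choice([-1, 1]) * rng.uniform(30, 80)
        y[k] += rng.choice([-1, 1]) * rng.uniform(30, 80)
    lon, lat = plane.to_lonlat(x, y)
    df["lon"], df["lat"] = lon, lat
    return df


def test_sda_matches_brute_force_oracle(rng, plane):
    for _ in range(3):
        df = _noisy_track(rng, plane)
        kept, reports = sda_filter(df)
        oracle = brute_force_sda(df)
        assert len(kept) == len(oracle)
        np.testing.assert_allclose(np.sort(kept["lon"].to_numpy()),
                                   np.sort(oracle["lon"].to_numpy()))
        rep = reports["A"]
        assert rep.n_kept == len(kept)
        assert rep.n_input == len(df)


def test_sda_idempotent(rng, plane):
    df = _noisy_track(rng, plane)
    once, _ = sda_filter(df)
    twice, reports = sda_filter(once)
    assert reports["A"].n_removed_speed == 0
    assert reports["A"].n_removed_spike == 0
    pd.testing.assert_frame_equal(once, twice)


def test_sda_never_removes_first_location(plane):
    # first point far from the rest: removing it would reconcile the speeds,
    # but the rule only ever drops interior points
    times = pd.date_range("2010-07-01", periods=5, freq="1h", tz="UTC")
    x = np.array([100.0, 0.0, 0.5, 1.0, 1.5])
    lon, lat = plane.to_lonlat(x, np.zeros(5))
    df = pd.DataFrame({"animal_id": "A", "time": times, "lon": lon, "lat": lat,
                       "loc_class": "3"})
    kept, _ = sda_filter(df)
    assert kept["lon"].iloc[0] == pytest.approx(lon[0])


def test_sda_short_track_passthrough(plane):
    df = make_track_frame(np.random.default_rng(0), plane, n=2)
    with pytest.warns(UserWarning, match="passthrough"):
        kept, reports = sda_filter(df)
    assert len(kept) == 2


# ---------------------------------------------------------------------------
# Haul-out detection
# ---------------------------------------------------------------------------


def test_detect_haulouts_threshold():
    times = pd.date_range("2010-07-01", periods=13, freq="5min", tz="UTC")
    dry = [False, True, True, False,            # 10-min spell: not enough
           True, True, True, True, False,       # 20-min spell: haul-out
           False, True, True, True]             # trailing spell to end: 10 min
    df = pd.DataFrame({"animal_id": "A", "time": times, "dry": dry})
    out = detect_haulouts(df, min_dry_minutes=10.0)
    assert len(out) == 1
    assert out["start"].iloc[0] == times[4]
    assert out["end"].iloc[0] == times[8]


def test_detect_haulouts_trailing_spell_counts_when_long():
    times = pd.date_range("2010-07-01", periods=8, freq="10min", tz="UTC")
    df = pd.DataFrame({"animal_id": "A", "time": times,
                       "dry": [False, False, True, True, True, True, True, True]})
    out = detect_haulouts(df, min_dry_minutes=30.0)
    assert len(out) == 1
    assert out["end"].iloc[0] == times[-1]


# ---------------------------------------------------------------------------
# CTCRW fit + geolocation
# ---------------------------------------------------------------------------


def _simulate_ctcrw(rng, plane, n=150, beta=0.7, sigma=1.5, dt_h=1.0,
                    obs_sd_km=0.3):
    """Exact discretization of the OU-velocity process plus noisy fixes."""
    a = np.exp(-beta * dt_h)
    qvv = sigma**2 * (1 - a * a) / (2 * beta)
    x = np.zeros(n)
    y = np.zeros(n)
    vx = vy = 0.0
    for k in range(1, n):
        x[k] = x[k - 1] + vx * (1 - a) / beta
        y[k] = y[k - 1] + vy * (1 - a) / beta
        vx = a * vx + rng.normal(0, np.sqrt(qvv))
        vy = a * vy + rng.normal(0, np.sqrt(qvv))
    times = pd.date_range("2010-07-01", periods=n, freq=f"{int(dt_h*60)}min", tz="UTC")
    lon, lat = plane.to_lonlat(x + rng.normal(0, obs_sd_km, n),
                               y + rng.normal(0, obs_sd_km, n))
    obs = pd.DataFrame({"animal_id": "A", "time": times, "lon": lon, "lat": lat,
                        "loc_class": "3"})
    truth_lon, truth_lat = plane.to_lonlat(x, y)
    return obs, pd.DataFrame({"time": times, "lon": truth_lon, "lat": truth_lat})


def test_fit_track_and_locate_recover_positions(rng, plane):
    obs, truth = _simulate_ctcrw(rng, plane)
    model = fit_track(obs, fit_error_scale=False,
                      class_sd_km={"3": 0.3})
    pos = locate(model, truth["time"])
    err = haversine_km(pos["lon"], pos["lat"], truth["lon"], truth["lat"])
    # smoothing must beat the raw 0.3 km observation noise
    raw = haversine_km(obs["lon"], obs["lat"], truth["lon"], truth["lat"])
    assert np.median(err) < np.median(raw)
    assert np.median(err) < 0.3


def test_fit_track_interpolates_between_fixes(rng, plane):
    obs, truth = _simulate_ctcrw(rng, plane)
    model = fit_track(obs, fit_error_scale=False, class_sd_km={"3": 0.3})
    mid = truth["time"][:-1] + pd.Timedelta(minutes=30)
    pos = locate(model, mid)
    # interpolated positions stay between the bracketing truth scale
    seg = haversine_km(pos["lon"], pos["lat"],
                       truth["lon"][:-1].to_numpy(), truth["lat"][:-1].to_numpy())
    assert np.median(seg) < 1.0


def test_locate_out_of_span_raises(rng, plane):
    obs, _ = _simulate_ctcrw(rng, plane, n=50)
    model = fit_track(obs, fit_error_scale=False, class_sd_km={"3": 0.3})
    with pytest.raises(DataError, match="outside model span"):
        locate(model, [obs["time"].iloc[-1] + pd.Timedelta(days=2)])


def test_fit_track_rejects_multiple_animals(rng, plane):
    obs, _ = _simulate_ctcrw(rng, plane, n=30)
    obs.loc[obs.index[-5:], "animal_id"] = "B"
    with pytest.raises(DataError, match="single animal"):
        fit_track(obs)


def test_haulout_freezes_position(rng, plane):
    obs, truth = _simulate_ctcrw(rng, plane, n=100)
    ho = pd.DataFrame({"start": [obs["time"].iloc[40]],
                       "end": [obs["time"].iloc[60]]})
    model = fit_track(obs, haulouts=ho, fit_error_scale=False,
                      class_sd_km={"3": 0.3})
    inside = pd.date_range(obs["time"].iloc[42], obs["time"].iloc[58], freq="2h")
    pos = locate(model, inside)
    spread = haversine_km(pos["lon"].iloc[0], pos["lat"].iloc[0],
                          pos["lon"], pos["lat"])
    # the frozen interval collapses to (nearly) one point
    assert float(np.max(spread)) < 1e-6
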