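"""Shared fixtures and synthetic-data helpers for the test suite."""

import numpy as np
import pandas as pd
import pytest

from sealdive.geo import LocalPlane
from sealdive.hydro import CTDCast


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plane():
    return LocalPlane(13.0, 78.2)


def make_track_frame(rng, plane, n=200, animal="A", step_h=1.0,
                     walk_sd_km=1.0, start="2010-07-01"):
    """A plausible random-walk Argos table in lon/lat with class-3 fixes."""
    times = pd.date_range(start, periods=n, freq=f"{int(step_h * 60)}min", tz="UTC")
    x = np.cumsum(rng.normal(0, walk_sd_km, n))
    y = np.cumsum(rng.normal(0, walk_sd_km, n))
    lon, lat = plane.to_lonlat(x, y)
    return pd.DataFrame({"animal_id": animal, "time": times,
                         "lon": lon, "lat": lat, "loc_class": "3"})


def make_cast(cast_id="C1", animal="A", time="2010-10-01T06:00:00Z",
              lon=12.8, lat=78.2, depths=None, temps=None, sals=None):
    depths = np.arange(3.0, 80.0, 5.0) if depths is None else np.asarray(depths, float)
    temps = np.full(len(depths), 4.0) if temps is None else np.asarray(temps, float)
    sals = np.full(len(depths), 34.3) if sals is None else np.asarray(sals, float)
    return CTDCast(cast_id=cast_id, animal_id=animal,
                   time=pd.Timestamp(time), lon=lon, lat=lat,
                   depth_m=depths, temp_c=temps, sal_psu=sals)


def random_casts(rng, n=50):
    """A batch of varied casts for oracle comparisons."""
    casts = []
    t0 = pd.Timestamp("2010-10-01", tz="UTC")
    for i in range(n):
        zmax = rng.uniform(40, 160)
        z = np.arange(3.0, zmax, 5.0)
        casts.append(make_cast(
            cast_id=f"C{i:03d}", animal=f"S{i % 5}",
            time=t0 + pd.Timedelta(hours=float(rng.uniform(0, 400))),
            lon=13.0 + rng.normal(0, 0.3), lat=78.2 + rng.normal(0, 0.1),
            depths=z,
            temps=4.0 + rng.normal(0, 0.5, len(z)),
            sals=34.3 + rng.normal(0, 0.05, len(z))))
    return casts
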