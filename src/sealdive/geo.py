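"""Spherical-earth geodesy used throughout the pipeline.

Distances for track filtering use the haversine formula on a sphere of radius
6371 km; the state-space movement model and the time-spent-in-area grid work in
a local equirectangular tangent plane centred on the study region.  At the
spatial scale of a harbour seal's range (< 100 km) the distortion of either
approximation is negligible relative to Argos location error.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


class LocalPlane:
    """Equirectangular projection about a reference point.

    x increases eastward, y northward, both in km.  Inverse of :meth:`to_xy`
    is :meth:`to_lonlat`; the pair round-trips to machine precision.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._coslat = np.cos(np.radians(lat0))

    def to_xy(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = np.radians(lon - self.lon0) * EARTH_RADIUS_KM * self._coslat
        y = np.radians(lat - self.lat0) * EARTH_RADIUS_KM
        return x, y

    def to_lonlat(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = self.lon0 + np.degrees(x / (EARTH_RADIUS_KM * self._coslat))
        lat = self.lat0 + np.degrees(y / EARTH_RADIUS_KM)
        return lon, lat


def turning_angle_deg(lon_prev, lat_prev, lon_v, lat_v, lon_next, lat_next):
    """Interior angle at a track vertex, in degrees.

    0 deg means a full reversal (the out-leg doubles back along the in-leg);
    180 deg means the three points are collinear in travel order.  Computed in
    the tangent plane at each vertex, adequate for the few-km legs the spike
    filter inspects.  Accepts scalars or arrays of vertices; a degenerate leg
    (zero length) yields 180 deg.
    """
    lon_prev, lat_prev, lon_v, lat_v, lon_next, lat_next = (
        np.asarray(x, dtype=float)
        for x in (lon_prev, lat_prev, lon_v, lat_v, lon_next, lat_next))
    coslat = np.cos(np.radians(lat_v))
    ax = np.radians(lon_prev - lon_v) * EARTH_RADIUS_KM * coslat
    ay = np.radians(lat_prev - lat_v) * EARTH_RADIUS_KM
    bx = np.radians(lon_next - lon_v) * EARTH_RADIUS_KM * coslat
    by = np.radians(lat_next - lat_v) * EARTH_RADIUS_KM
    na = np.hypot(ax, ay)
    nb = np.hypot(bx, by)
    denom = na * nb
    safe = denom > 0.0
    cosang = np.where(safe, (ax * bx + ay * by) / np.where(safe, denom, 1.0), -1.0)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang = np.where(safe, ang, 180.0)
    return float(ang) if ang.ndim == 0 else ang
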