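"""Per-dive and per-day behavioural metrics.

Bottom time from broken-stick profiles, daily summaries, per-animal diving
effort residuals, bathymetry-relative dive classification, diel period bins,
and the time-spent-in-area (TSA) grid with top-quartile high-usage cells.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError
from .io import OUTSIDE_DOMAIN, RasterGrid
from .tracks import TrackModel, locate

log = logging.getLogger(__name__)

BOTTOM_FRACTION = 0.8         # bottom time = time deeper than 80% of max depth
COASTAL_BATHY_M = 50.0        # waters shallower than this are 'coastal'
BENTHIC_RATIO = 0.95          # depth/bathymetry ratio above which a dive is benthic


# ---------------------------------------------------------------------------
# Bottom time
# ---------------------------------------------------------------------------

def profile_points(duration_s: float, t_offsets, depths):
    """Full piecewise-linear profile: surface endpoints around the 4
    transmitted inflection points.

    Returns (times, depths) arrays of length 6.  Offsets must be strictly
    increasing inside (0, duration).
    """
    t = np.asarray(t_offsets, dtype=float)
    d = np.asarray(depths, dtype=float)
    if np.any(np.diff(t) <= 0) or t[0] <= 0 or t[-1] >= duration_s:
        raise DataError("profile: inflection offsets must increase strictly inside (0, duration)")
    return np.concatenate([[0.0], t, [duration_s]]), np.concatenate([[0.0], d, [0.0]])


def bottom_time(duration_s: float, max_depth_m: float, t_offsets, depths,
                fraction: float = BOTTOM_FRACTION) -> float:
    """Seconds spent strictly deeper than ``fraction`` x max depth.

    The broken-stick profile is interpolated linearly and threshold crossings
    are solved exactly on each segment; touching the threshold without
    crossing contributes zero measure.
    """
    tt, dd = profile_points(duration_s, t_offsets, depths)
    thr = fraction * max_depth_m
    total = 0.0
    for i in range(len(tt) - 1):
        t0, t1 = tt[i], tt[i + 1]
        d0, d1 = dd[i], dd[i + 1]
        if d0 > thr and d1 > thr:
            total += t1 - t0
        elif d0 > thr or d1 > thr:
            # one exact crossing inside the segment
            tc = t0 + (thr - d0) / (d1 - d0) * (t1 - t0)
            total += (tc - t0) if d0 > thr else (t1 - tc)
    return total


def bottom_time_table(dives: pd.DataFrame) -> pd.Series:
    """Bottom time for every row of a dive table (see io schema)."""
    out = np.empty(len(dives))
    t_cols = dives[["t1", "t2", "t3", "t4"]].to_numpy(dtype=float)
    d_cols = dives[["d1", "d2", "d3", "d4"]].to_numpy(dtype=float)
    dur = dives["duration_s"].to_numpy(dtype=float)
    mx = dives["max_depth_m"].to_numpy(dtype=float)
    for i in range(len(dives)):
        out[i] = bottom_time(dur[i], mx[i], t_cols[i], d_cols[i])
    return pd.Series(out, index=dives.index, name="bottom_time_s")


# ---------------------------------------------------------------------------
# Daily series from 6-h summaries
# ---------------------------------------------------------------------------

def daily_series(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-animal daily aggregates from 6-hour summary records.

    A day is ``complete`` only when exactly the four periods 00/06/12/18 are
    present; incomplete days are kept in the output but flagged, and model
    inputs should filter on the flag.  Daily depth/duration are means over
    the periods, counts and diving time are sums, and the dive/surface ratio
    is total diving time over total surface time.
    """
    df = summaries.copy()
    df["date"] = df["period_start"].dt.floor("D")
    dup = df.duplicated(subset=["animal_id", "date", "period_start"])
    if dup.any():
        raise DataError("daily_series: duplicate 6-h period for an animal-day")
    rows = []
    for (animal, date), grp in df.groupby(["animal_id", "date"], sort=True):
        complete = len(grp) == 4
        surface = grp["surface_time_s"].sum()
        diving = grp["time_diving_s"].sum()
        rows.append({
            "animal_id": animal, "date": date,
            "depth_m": grp["avg_depth_m"].mean(),
            "duration_s": grp["avg_duration_s"].mean(),
            "n_dives": int(grp["n_dives"].sum()),
            "time_diving_s": diving,
            "surface_time_s": surface,
            "dive_surface_ratio": diving / surface if surface > 0 else np.nan,
            "complete": complete,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diving-effort residuals
# ---------------------------------------------------------------------------

def effort_residuals(dives: pd.DataFrame, min_dives: int = 10) -> pd.DataFrame:
    """Standardized residuals of bottom time ~ max depth + duration, per animal.

    Positive residuals mark dives with a longer bottom time than expected for
    their depth and duration (higher foraging effort).  Residuals are divided
    by their per-animal standard deviation, so each animal's residual vector
    has mean 0 and SD 1.  Animals with fewer than ``min_dives`` dives are
    skipped with a warning; a rank-deficient design (constant depth *and*
    duration) raises :class:`DataError`.
    """
    if "bottom_time_s" not in dives.columns:
        dives = dives.assign(bottom_time_s=bottom_time_table(dives))
    parts = []
    for animal, grp in dives.groupby("animal_id", sort=False):
        if len(grp) < min_dives:
            warnings.warn(f"effort_residuals: animal {animal} has <{min_dives} dives; skipped")
            continue
        X = sm.add_constant(grp[["max_depth_m", "duration_s"]].to_numpy(dtype=float))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DataError(f"effort_residuals: rank-deficient design for animal {animal}")
        fit = sm.OLS(grp["bottom_time_s"].to_numpy(dtype=float), X).fit()
        resid = fit.resid
        sd = resid.std(ddof=0)
        if sd == 0:
            std_resid = np.zeros(len(resid))
        else:
            std_resid = resid / sd
        parts.append(pd.DataFrame({"effort_residual": std_resid}, index=grp.index))
    if not parts:
        return dives.iloc[0:0].assign(effort_residual=[])
    res = pd.concat(parts)
    return dives.join(res, how="inner")


# ---------------------------------------------------------------------------
# Dive classification
# ---------------------------------------------------------------------------

def classify_dive(max_depth_m: float, bathy_depth_m) -> str:
    """'coastal' | 'benthic' | 'pelagic' | 'unclassified'.

    Coastal when the water column is shallower than 50 m; otherwise the dive
    depth / bathymetric depth ratio decides: > 0.95 benthic, otherwise
    pelagic (a ratio of exactly 0.95 is assigned to pelagic).  Nodata
    bathymetry yields 'unclassified'.
    """
    if bathy_depth_m is OUTSIDE_DOMAIN or bathy_depth_m is None or \
            (isinstance(bathy_depth_m, float) and not np.isfinite(bathy_depth_m)):
        return "unclassified"
    if bathy_depth_m <= 0:
        return "unclassified"
    if bathy_depth_m < COASTAL_BATHY_M:
        return "coastal"
    return "benthic" if max_depth_m / bathy_depth_m > BENTHIC_RATIO else "pelagic"


def classify_dives(dives: pd.DataFrame, bathy: RasterGrid) -> pd.Series:
    """Classify every located dive (needs lon/lat columns) against bathymetry."""
    vals, inside = bathy.lookup_many(dives["lon"].to_numpy(), dives["lat"].to_numpy())
    vals = np.where(vals == bathy.nodata, np.nan, vals)
    labels = [classify_dive(d, (b if np.isfinite(b) else OUTSIDE_DOMAIN))
              for d, b in zip(dives["max_depth_m"].to_numpy(), vals)]
    n_bad = sum(1 for lab in labels if lab == "unclassified")
    if n_bad:
        log.info("classify_dives: %d dives unclassified (nodata bathymetry)", n_bad)
    return pd.Series(labels, index=dives.index, name="dive_class")


# ---------------------------------------------------------------------------
# Diel bins
# ---------------------------------------------------------------------------

def diel_bin(t) -> str:
    """Half-open hour bins: night_am [0,6), day [6,18), night_pm [18,24)."""
    h = pd.Timestamp(t).hour
    if h < 6:
        return "night_am"
    if h < 18:
        return "day"
    return "night_pm"


def diel_period(t) -> str:
    """'night' (00-06 and 18-24) vs 'day' (06-18), the modelling dichotomy."""
    return "day" if diel_bin(t) == "day" else "night"


# ---------------------------------------------------------------------------
# Time spent in area
# ---------------------------------------------------------------------------


@dataclass
class TSAResult:
    """Per-animal time-in-cell allocation on a square km grid."""

    animal_id: str
    cell_km: float
    cells: dict = field(default_factory=dict)     # (ix, iy) -> seconds
    high_usage: set = field(default_factory=set)  # cell keys in the top quartile

    @property
    def total_seconds(self) -> float:
        return float(sum(self.cells.values()))

    def cell_key(self, x_km: float, y_km: float):
        return (math.floor(x_km / self.cell_km), math.floor(y_km / self.cell_km))


def _allocate_segment(cells: dict, x0, y0, x1, y1, dt_s, cell_km):
    """Split a straight segment's elapsed time across the grid cells it
    crosses, proportionally to in-cell length.  Exact: crossing parameters of
    the grid lines are solved analytically."""
    if dt_s <= 0:
        return
    dx, dy = x1 - x0, y1 - y0
    params = [0.0, 1.0]
    if dx != 0.0:
        i_lo, i_hi = sorted((x0 / cell_km, x1 / cell_km))
        for i in range(math.floor(i_lo) + 1, math.ceil(i_hi)):
            params.append((i * cell_km - x0) / dx)
    if dy != 0.0:
        j_lo, j_hi = sorted((y0 / cell_km, y1 / cell_km))
        for j in range(math.floor(j_lo) + 1, math.ceil(j_hi)):
            params.append((j * cell_km - y0) / dy)
    params = sorted(p for p in params if 0.0 <= p <= 1.0)
    for a, b in zip(params[:-1], params[1:]):
        if b <= a:
            continue
        tm = (a + b) / 2.0
        key = (math.floor((x0 + tm * dx) / cell_km), math.floor((y0 + tm * dy) / cell_km))
        cells[key] = cells.get(key, 0.0) + dt_s * (b - a)


def compute_tsa(model: TrackModel, cell_km: float = 5.0, step_minutes: float = 10.0,
                quantile: float = 0.75) -> TSAResult:
    """Time-spent-in-area grid from the smoothed track.

    The track is sampled at a fixed step; each inter-sample segment's
    non-haul-out elapsed time is distributed over the cells it crosses by
    exact in-cell length fraction.  Cells with TSA at or above the
    ``quantile`` of the positive-TSA cells are marked high-usage; with heavy
    ties the marked set is capped at the top quarter of cells by TSA so the
    rule stays a top-25% rule.
    """
    t0, t1 = model.span
    if t1 <= t0:
        raise DataError("compute_tsa: empty track")
    times_s = np.arange(t0, t1 + 1e-9, step_minutes * 60.0)
    if times_s[-1] < t1:
        times_s = np.append(times_s, t1)
    times = pd.to_datetime(times_s * 1e9, utc=True)
    pos = locate(model, times)
    x, y = model.plane.to_xy(pos["lon"].to_numpy(), pos["lat"].to_numpy())
    res = TSAResult(animal_id=model.animal_id, cell_km=cell_km)
    for k in range(len(times_s) - 1):
        dt = times_s[k + 1] - times_s[k]
        moving = dt
        for s, e in model.haulouts_s:
            moving -= max(0.0, min(times_s[k + 1], e) - max(times_s[k], s))
        _allocate_segment(res.cells, x[k], y[k], x[k + 1], y[k + 1],
                          max(moving, 0.0), cell_km)
    positive = [(v, key) for key, v in res.cells.items() if v > 0]
    if positive:
        vals = np.array([v for v, _ in positive])
        thr = np.quantile(vals, quantile)
        marked = [key for v, key in positive if v >= thr]
        cap = math.ceil((1.0 - quantile) * len(positive))
        if len(marked) > cap:
            marked = [key for v, key in
                      sorted(positive, key=lambda t: -t[0])[:cap]]
        res.high_usage = set(marked)
    return res


def high_usage_dives(dives: pd.DataFrame, tsa: TSAResult, plane) -> pd.Series:
    """Boolean mask of dives located inside the animal's high-usage cells."""
    x, y = plane.to_xy(dives["lon"].to_numpy(), dives["lat"].to_numpy())
    keys = [tsa.cell_key(xi, yi) for xi, yi in zip(x, y)]
    return pd.Series([k in tsa.high_usage for k in keys], index=dives.index,
                     name="high_usage")
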