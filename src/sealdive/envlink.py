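"""Linking hydrography to diving: the MLD-vs-dive-depth divergence series,
single mean-shift change-point detection, and lagged wind covariates used as
an upwelling proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

# air density and drag coefficient for the optional wind-stress conversion
RHO_AIR = 1.25        # kg m-3
DRAG_COEFF = 1.3e-3


# ---------------------------------------------------------------------------
# Divergence series
# ---------------------------------------------------------------------------

def divergence_series(daily_dive_depth: pd.DataFrame, daily_mld: pd.DataFrame) -> pd.DataFrame:
    """Daily difference between the mixed-layer depth and mean dive depth.

    Inputs are animal-pooled daily frames: ``daily_dive_depth`` (date,
    mean_dive_depth) restricted to shelf dives, and ``daily_mld`` (date, mld).
    The output covers the union of dates with ``diff = mld - mean_dive_depth``
    defined only where both terms are present (missing days stay NaN — gaps,
    never zeros).  A 3-day triangular moving mean is added as ``diff_smooth``
    for presentation only; analyses must use the raw ``diff``.
    """
    a = daily_dive_depth[["date", "mean_dive_depth"]].set_index("date")
    b = daily_mld[["date", "mld"]].set_index("date")
    if a.index.intersection(b.index).empty:
        raise DataError("divergence_series: no overlapping dates")
    merged = a.join(b, how="outer").sort_index()
    full = pd.date_range(merged.index.min(), merged.index.max(), freq="D")
    merged = merged.reindex(full)
    merged.index.name = "date"
    merged["diff"] = merged["mld"] - merged["mean_dive_depth"]
    # 3-day triangular window, centred, renormalized over available neighbours
    w = np.array([0.25, 0.5, 0.25])
    vals = merged["diff"].to_numpy()
    sm = np.full(len(vals), np.nan)
    for i in range(len(vals)):
        lo, hi = max(i - 1, 0), min(i + 2, len(vals))
        seg = vals[lo:hi]
        ww = w[lo - i + 1:hi - i + 1]
        ok = np.isfinite(seg)
        if ok.any() and np.isfinite(vals[i]):
            sm[i] = np.average(seg[ok], weights=ww[ok])
    merged["diff_smooth"] = sm
    return merged.reset_index()


# ---------------------------------------------------------------------------
# Change point (single mean shift, AMOC-style)
# ---------------------------------------------------------------------------


@dataclass
class ChangePointResult:
    """Best single mean shift in a daily series."""

    change_date: pd.Timestamp | None
    change_index: int | None
    pre_mean: float
    post_mean: float
    statistic: float          # 2 x log likelihood ratio
    penalty: float
    significant: bool


def change_point(series: pd.DataFrame | pd.Series, value_col: str = "diff",
                 penalty: float | None = None, min_segment: int = 2) -> ChangePointResult:
    """At-most-one-change in the mean under a normal likelihood.

    The statistic is the maximum over admissible split points of
    ``n log(RSS0 / RSS(tau))`` (twice the Gaussian log likelihood ratio with
    common unknown variance); the change is significant when it exceeds the
    penalty (default ``3 log n``, an MBIC-flavoured constant, configurable).
    NaN days are dropped before analysis.  Requires >= 20 values; the change
    date is strictly inside the series span.
    """
    if isinstance(series, pd.Series):
        df = series.rename("value").reset_index()
        df.columns = ["date", "value"]
    else:
        df = series[["date", value_col]].rename(columns={value_col: "value"})
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    if n < 20:
        raise DataError(f"change_point: series too short ({n} < 20 values)")
    if penalty is None:
        penalty = 3.0 * np.log(n)
    css = np.cumsum(y)
    css2 = np.cumsum(y * y)
    rss0 = css2[-1] - css[-1] ** 2 / n
    best_stat, best_tau = -np.inf, None
    for tau in range(min_segment, n - min_segment + 1):
        s1, s2 = css[tau - 1], css[-1] - css[tau - 1]
        q1, q2 = css2[tau - 1], css2[-1] - css2[tau - 1]
        rss = (q1 - s1**2 / tau) + (q2 - s2**2 / (n - tau))
        if rss <= 0:
            stat = np.inf if rss0 > 0 else 0.0
        else:
            stat = n * np.log(rss0 / rss)
        if stat > best_stat:
            best_stat, best_tau = stat, tau
    pre = float(y[:best_tau].mean())
    post = float(y[best_tau:].mean())
    return ChangePointResult(
        change_date=pd.Timestamp(df["date"].iloc[best_tau]),
        change_index=int(best_tau),
        pre_mean=pre, post_mean=post,
        statistic=float(best_stat), penalty=float(penalty),
        significant=bool(best_stat > penalty))


# ---------------------------------------------------------------------------
# Wind covariates
# ---------------------------------------------------------------------------

def wind_from_bearing(u, v, from_convention: bool = False):
    """Direction-of-origin bearing in degrees (0 = from north, 90 = from east).

    ``u``/``v`` are blowing-toward components by default; set
    ``from_convention`` if the inputs are already meteorological
    from-components.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not from_convention:
        u, v = -u, -v
    return np.degrees(np.arctan2(u, v)) % 360.0


def _in_sector(bearing, sector: str):
    b = np.asarray(bearing, dtype=float)
    if sector == "N":
        return (b >= 315.0) | (b < 45.0)
    if sector in ("NE", "N+E"):
        return (b >= 315.0) | (b < 135.0)
    raise DataError(f"wind_covariates: unknown sector '{sector}'")


def wind_covariates(wind: pd.DataFrame, dates, lag_days: int, sector: str = "N",
                    from_convention: bool = False, as_stress: bool = False) -> pd.DataFrame:
    """Mean directional wind over the ``lag_days`` window preceding each date.

    A record contributes when its direction of origin falls in the sector:
    'N' is within +/-45 deg of true north; 'NE' is the contiguous band from
    north through east (+/-45 deg around both, i.e. bearings 315..135).  The
    covariate for date d averages the speed (or wind stress
    ``rho_air C_d |U|^2`` when ``as_stress``) of contributing records in
    [d - lag, d); it is 0 when no record qualifies.  A window whose record
    count falls below half the expected cadence coverage is flagged.
    """
    if lag_days < 1:
        raise DataError("wind_covariates: lag must be >= 1 day")
    w = wind.sort_values("time", kind="stable")
    tcol = w["time"]
    if getattr(tcol.dt, "tz", None) is not None:
        tcol = tcol.dt.tz_convert("UTC").dt.tz_localize(None)
    t = tcol.to_numpy(dtype="datetime64[ns]")
    u = w["u"].to_numpy(dtype=float)
    v = w["v"].to_numpy(dtype=float)
    speed = np.hypot(u, v)
    magnitude = RHO_AIR * DRAG_COEFF * speed**2 if as_stress else speed
    bearing = wind_from_bearing(u, v, from_convention)
    in_sec = _in_sector(bearing, sector)
    steps = pd.Series(t).diff().dropna()
    cadence_s = steps.mode().iloc[0].total_seconds() if len(steps) else 86_400.0
    expected = lag_days * 86_400.0 / cadence_s

    dates = pd.DatetimeIndex(pd.to_datetime(dates))
    if dates.tz is not None:
        dates = dates.tz_convert("UTC").tz_localize(None)
    rows = []
    for d in dates:
        lo = d - pd.Timedelta(days=lag_days)
        mask = (t >= np.datetime64(lo)) & (t < np.datetime64(d))
        n_window = int(mask.sum())
        contributing = mask & in_sec
        val = float(magnitude[contributing].mean()) if contributing.any() else 0.0
        rows.append({"date": d, "lag_days": lag_days, "sector": sector,
                     "value": val, "n_records": int(contributing.sum()),
                     "flagged": n_window < 0.5 * expected})
    return pd.DataFrame(rows)
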