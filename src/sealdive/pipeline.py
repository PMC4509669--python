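"""End-to-end orchestration and evaluation helpers.

The building blocks live in their own modules (tracks, dives, hydro, models,
envlink); this module wires them into the standard processing chain —

    raw Argos + saltwater switch  ->  SDA filter  ->  CTCRW fit per animal
    dive records                  ->  geolocation ->  bathymetric dive classes
    dive records + casts          ->  daily series, seasonal/diel/wind models

— and provides the evaluation routines that score pipeline output against a
simulation's ground truth (class agreement, mixed-layer-depth recovery,
seasonal-curve coverage, change-point calibration, diel detection).  Every
analysis script and test goes through these functions, so the computation is
defined exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dives import classify_dives, diel_period
from .envlink import change_point, divergence_series
from .errors import DataError
from .hydro import casts_from_frame, mld_table
from .io import RasterGrid
from .models import ModelFit, ModelSpec, SmoothTerm, fit_amm
from .simulate import simulate_divergence_series
from .tracks import FilterReport, TrackModel, detect_haulouts, fit_track, locate, sda_filter

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Track stage
# ---------------------------------------------------------------------------


@dataclass
class TrackSet:
    """Per-animal fitted movement models plus the filtering bookkeeping."""

    models: dict = field(default_factory=dict)        # animal_id -> TrackModel
    kept: pd.DataFrame | None = None                  # SDA-filtered locations
    reports: dict = field(default_factory=dict)       # animal_id -> FilterReport
    haulouts: dict = field(default_factory=dict)      # animal_id -> DataFrame


def fit_tracks(argos: pd.DataFrame, dry: pd.DataFrame | None = None,
               min_dry_minutes: float = 10.0, **fit_kw) -> TrackSet:
    """SDA-filter the Argos table and fit a CTCRW per animal.

    ``dry`` is the optional saltwater-switch record used to detect haul-outs,
    during which the movement model is frozen.
    """
    kept, reports = sda_filter(argos)
    out = TrackSet(kept=kept, reports=reports)
    for animal, grp in kept.groupby("animal_id", sort=False):
        ho = None
        if dry is not None:
            ho = detect_haulouts(dry[dry["animal_id"] == animal],
                                 min_dry_minutes=min_dry_minutes)
        out.haulouts[animal] = ho
        out.models[animal] = fit_track(grp, ho, **fit_kw)
    return out

def locate_dives(tracks: TrackSet, dives: pd.DataFrame,
                 time_col: str = "start") -> pd.DataFrame:
    """Attach smoothed (lon, lat) to every dive via its animal's track model.

    Rows whose animal has no fitted model raise :class:`DataError` — silently
    dropping dives would bias every downstream composition estimate.
    """
    missing = set(dives["animal_id"]) - set(tracks.models)
    if missing:
        raise DataError(f"locate_dives: no track model for {sorted(missing)}")
    out = dives.copy()
    out["lon"] = np.nan
    out["lat"] = np.nan
    for animal, grp in dives.groupby("animal_id", sort=False):
        pos = locate(tracks.models[animal], grp[time_col])
        out.loc[grp.index, "lon"] = pos["lon"].to_numpy()
        out.loc[grp.index, "lat"] = pos["lat"].to_numpy()
    return out


def classify_located_dives(dives: pd.DataFrame, bathy: RasterGrid) -> pd.DataFrame:
    """Add the bathymetry-relative ``dive_class`` column to located dives."""
    out = dives.copy()
    out["dive_class"] = classify_dives(out, bathy)
    return out


def class_agreement(labels, truth_labels) -> float:
    """Fraction of dives whose pipeline class matches the ground-truth class."""
    a = np.asarray(labels, dtype=object)
    b = np.asarray(truth_labels, dtype=object)
    if len(a) != len(b) or len(a) == 0:
        raise DataError("class_agreement: label vectors must be equal, non-zero length")
    return float(np.mean(a == b))


# ---------------------------------------------------------------------------
# Daily series
# ---------------------------------------------------------------------------


def _naive_dates(ts: pd.Series) -> pd.Series:
    if getattr(ts.dt, "tz", None) is not None:
        ts = ts.dt.tz_convert("UTC").dt.tz_localize(None)
    return ts.dt.normalize()


def pooled_daily_depth(dives: pd.DataFrame, time_col: str = "start",
                       depth_col: str = "max_depth_m",
                       exclude_dates=()) -> pd.DataFrame:
    """Dive-pooled daily mean depth across all animals.

    Pooling at the dive level (every dive weighted equally) keeps the daily
    series an unbiased estimate of the population mixture the generator's
    expectation curve describes; ``exclude_dates`` (ISO strings) drops known
    perturbation days.  The result carries a constant ``animal_id`` so it can
    feed the single-series AR(1) smoother directly.
    """
    d = dives.copy()
    d["date"] = _naive_dates(d[time_col])
    if exclude_dates:
        excl = {str(pd.Timestamp(x).date()) for x in exclude_dates}
        d = d[~d["date"].dt.strftime("%Y-%m-%d").isin(excl)]
    daily = d.groupby("date")[depth_col].mean().reset_index()
    daily = daily.rename(columns={depth_col: "depth_m"})
    daily["animal_id"] = "ALL"
    return daily


def seasonal_depth_fit(daily: pd.DataFrame, k: int = 24) -> ModelFit:
    """The seasonal depth smooth: f(date) with AR(1) errors on the pooled
    daily series (REML)."""
    spec = ModelSpec(response="depth_m", smooths=(SmoothTerm("date", k=k),),
                     group="animal_id", ar1=True, time_col="date",
                     name="seasonal_depth")
    return fit_amm(daily, spec, criterion="reml")


def curve_coverage(fit: ModelFit, truth_curve: pd.DataFrame, z: float = 1.96) -> dict:
    """How well a fitted curve's pointwise band covers a reference curve.

    ``truth_curve`` has columns (date, depth_m).  Returns the share of dates
    where |fit - truth| <= z * SE plus the error magnitudes.
    """
    pred = fit.predict(pd.DataFrame({"date": truth_curve["date"]}), se=True)
    err = pred["fit"].to_numpy() - truth_curve["depth_m"].to_numpy(dtype=float)
    se = pred["se"].to_numpy()
    return {"coverage": float(np.mean(np.abs(err) <= z * se)),
            "max_abs_err_m": float(np.max(np.abs(err))),
            "mean_se_m": float(np.mean(se)),
            "n_dates": int(len(err))}


# ---------------------------------------------------------------------------
# Hydrography recovery
# ---------------------------------------------------------------------------


def mld_recovery(cast_frame: pd.DataFrame, truth_mld: pd.DataFrame,
                 tol_m: float) -> dict:
    """Score per-cast MLD estimates against the true daily interface depth.

    Only casts with a valid, non-bottom-limited estimate are scored: a cast
    truncated above the mixed-layer base cannot observe the MLD, and the
    estimator flags exactly that condition.  ``truth_mld`` has columns
    (date, mld_m).
    """
    tab = mld_table(casts_from_frame(cast_frame))
    tab["date"] = _naive_dates(pd.to_datetime(tab["time"]))
    truth = truth_mld.copy()
    truth["date"] = pd.to_datetime(truth["date"]).dt.normalize()
    tab["truth_mld_m"] = tab["date"].map(truth.set_index("date")["mld_m"])
    usable = tab[tab["valid"] & ~tab["bottom_limited"]].dropna(
        subset=["mld_m", "truth_mld_m"])
    if usable.empty:
        raise DataError("mld_recovery: no usable casts")
    hit = (usable["mld_m"] - usable["truth_mld_m"]).abs() <= tol_m
    return {"rate": float(hit.mean()), "n_usable": int(len(usable)),
            "n_total": int(len(tab)), "tol_m": float(tol_m), "table": tab}


# ---------------------------------------------------------------------------
# Divergence + change point
# ---------------------------------------------------------------------------


def divergence_changepoint(dives: pd.DataFrame, daily_mld: pd.DataFrame,
                           time_col: str = "start",
                           depth_col: str = "max_depth_m",
                           class_col: str = "dive_class"):
    """Change point of the MLD-minus-pelagic-dive-depth divergence series.

    Restricts to pelagic dives (the component that tracks the mixed layer),
    pools daily, differences against the daily MLD and runs the single
    mean-shift detector.  Returns (ChangePointResult, divergence frame).
    """
    pel = dives[dives[class_col] == "pelagic"].copy()
    if pel.empty:
        raise DataError("divergence_changepoint: no pelagic dives")
    pel["date"] = _naive_dates(pel[time_col])
    daily = pel.groupby("date")[depth_col].mean().reset_index()
    daily = daily.rename(columns={depth_col: "mean_dive_depth"})
    mld = daily_mld.rename(columns={"mld_m": "mld"})[["date", "mld"]].copy()
    mld["date"] = pd.to_datetime(mld["date"]).dt.normalize()
    div = divergence_series(daily, mld)
    return change_point(div), div


def changepoint_replicates(n_reps: int = 200, n_days: int = 150,
                           change_index: int = 100, shift: float = 45.0,
                           noise_sd: float = 12.0, tol_days: int = 2,
                           seed: int = 0) -> dict:
    """Calibration of the change-point detector on cheap series replicates.

    Each replicate is a mean-shift series with white noise at the magnitudes
    the full generator produces (a ~45 m divergence jump against ~12 m daily
    noise); the score is the share of replicates whose detected change lands
    within ``tol_days`` of the injected index.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 424_243]))
    hits = 0
    errors = []
    for _ in range(n_reps):
        series = simulate_divergence_series(n_days, change_index, shift,
                                            noise_sd, rng=rng)
        res = change_point(series)
        err = abs(res.change_index - change_index)
        errors.append(err)
        hits += err <= tol_days
    return {"rate": hits / n_reps, "n_reps": n_reps,
            "mean_abs_err_days": float(np.mean(errors)),
            "tol_days": tol_days}


# ---------------------------------------------------------------------------
# Wind-lag linkage
# ---------------------------------------------------------------------------


def offshore_daily_depth(dives: pd.DataFrame, time_col: str = "start",
                         depth_col: str = "max_depth_m",
                         class_col: str = "dive_class",
                         classes=("pelagic", "benthic")) -> pd.DataFrame:
    """Daily mean depth of offshore dives, with the ``year`` factor the
    wind-lag candidate models require.  ``classes`` selects which dive
    classes count as offshore."""
    off = dives[dives[class_col].isin(list(classes))].copy()
    if off.empty:
        raise DataError("offshore_daily_depth: no offshore dives")
    off["date"] = _naive_dates(off[time_col])
    daily = off.groupby("date")[depth_col].mean().reset_index()
    daily = daily.rename(columns={depth_col: "offshore_depth"})
    daily["year"] = daily["date"].dt.year.astype(str)
    return daily


def wind_lag_selection(dives: pd.DataFrame, wind: pd.DataFrame, **kw) -> dict:
    """BIC selection over wind sectors and 1-7 day lags for pelagic depth.

    The response is the daily mean depth of pelagic dives only: the wind
    effect acts directly on pelagic dive depth, so mixing in benthic dives
    (whose depth is set by the bottom, not the water column) only adds
    composition noise and weakens the lag discrimination.  Returns the
    ``fit_wind_gam`` result dict augmented with the margin of the best lag
    over the best competing lag.
    """
    from .models import fit_wind_gam

    daily = offshore_daily_depth(dives, classes=("pelagic",), **kw)
    out = fit_wind_gam(daily, "offshore_depth", wind)
    tab = out["table"]
    others = tab[(tab["lag_days"] != out["best_lag"]) & (tab["lag_days"] > 0)]
    out["margin_bic"] = float(others["bic"].min() - tab["bic"].min()) \
        if len(others) else np.inf
    return out


# ---------------------------------------------------------------------------
# Diel detection
# ---------------------------------------------------------------------------


def diel_contrast_by_month(dives: pd.DataFrame, time_col: str = "start",
                           depth_col: str = "max_depth_m",
                           class_col: str = "dive_class",
                           exclude_dates=(), min_pairs: int = 10) -> pd.DataFrame:
    """Paired night-minus-day depth contrast of pelagic dives, per month.

    For each animal-date with both day and night pelagic dives, the contrast
    is the difference of the two mean depths; pairing within animal-date
    cancels the animal offset, the day-scale behavioural autocorrelation and
    the habitat composition of the day.  Per month, the presence of a diel
    offset is judged by BIC between the zero-mean and free-mean Gaussian
    models of the contrasts:

        dbic = n log(mean(d^2) / var(d)) - 2 log(n)

    (positive = the free mean is preferred = a diel effect is detected).
    Returns one row per month: (month, n_pairs, mean_diff_m, dbic, detected).
    """
    pel = dives[dives[class_col] == "pelagic"].copy()
    if pel.empty:
        raise DataError("diel_contrast_by_month: no pelagic dives")
    t = pel[time_col]
    if getattr(t.dt, "tz", None) is not None:
        t = t.dt.tz_convert("UTC").dt.tz_localize(None)
    pel["date"] = t.dt.normalize()
    if exclude_dates:
        excl = {str(pd.Timestamp(x).date()) for x in exclude_dates}
        pel = pel[~pel["date"].dt.strftime("%Y-%m-%d").isin(excl)]
    pel["period"] = [diel_period(v) for v in t.loc[pel.index]]
    agg = (pel.groupby(["animal_id", "date", "period"])[depth_col].mean()
           .unstack("period"))
    if not {"day", "night"}.issubset(agg.columns):
        raise DataError("diel_contrast_by_month: need both day and night dives")
    agg = agg.dropna(subset=["day", "night"]).reset_index()
    agg["diff"] = agg["night"] - agg["day"]
    agg["month"] = agg["date"].dt.month
    rows = []
    for month, grp in agg.groupby("month"):
        d = grp["diff"].to_numpy(dtype=float)
        n = len(d)
        if n < min_pairs:
            continue
        var_free = float(np.mean((d - d.mean()) ** 2))
        if var_free == 0.0:
            continue
        dbic = n * np.log(np.mean(d**2) / var_free) - 2.0 * np.log(n)
        rows.append({"month": int(month), "n_pairs": n,
                     "mean_diff_m": float(d.mean()), "dbic": float(dbic),
                     "detected": bool(dbic > 0)})
    out = pd.DataFrame(rows)
    # chronological within a deployment that crosses the new year
    return out.sort_values("month", key=lambda m: (m < 6) * 12 + m,
                           kind="stable").reset_index(drop=True)
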