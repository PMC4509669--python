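"""Argos track cleaning and continuous-time movement modelling.

Two stages: a speed-distance-angle (SDA) filter that strips implausible
locations, and a continuous-time correlated random walk (CTCRW, i.e. an
Ornstein-Uhlenbeck velocity process integrated into position) fitted per
animal by maximum likelihood through a Kalman filter, with movement frozen
during haul-out intervals.  The fitted model geolocates any timestamped event
(dive, CTD cast) by fixed-interval smoothing.

Geometry: great-circle (haversine) distances for the filter; a local
equirectangular plane (km) for the state-space model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import DataError, FitError
from .geo import LocalPlane, haversine_km, turning_angle_deg

log = logging.getLogger(__name__)

VMAX_MS = 2.0                                   # swimming-speed threshold
SPIKE_RULES = ((15.0, 2.5), (25.0, 5.0))        # (angle deg, leg length km)

#: Isotropic measurement SD per Argos location class, km.  The error-per-class
#: idea follows standard Argos processing; the magnitudes are configurable
#: defaults, not asserted values.
DEFAULT_CLASS_SD_KM = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 4.0, "A": 8.0, "B": 15.0}


@dataclass
class FilterReport:
    """Bookkeeping for one animal's pass through the SDA filter."""

    n_input: int
    n_removed_speed: int = 0
    n_removed_spike: int = 0
    removed_indices: list = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed_speed - self.n_removed_spike


def _implied_speeds_ms(times_s, lons, lats):
    """Speed (m/s) over each segment between consecutive locations."""
    d_km = haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:])
    dt = np.diff(times_s)
    with np.errstate(divide="ignore"):
        return np.where(dt > 0, d_km * 1000.0 / np.maximum(dt, 1e-12), np.inf)


def sda_filter(locs: pd.DataFrame, vmax_ms: float = VMAX_MS,
               spike_rules=SPIKE_RULES) -> tuple[pd.DataFrame, dict]:
    """Speed-distance-angle filter, applied per animal.

    A location violates the speed rule when the implied speed against *both*
    neighbours exceeds ``vmax_ms``; it is a spike when its turning angle is
    below a rule's angle threshold and both adjacent legs are longer than the
    rule's paired distance.  One location — the worst speed violator, else the
    sharpest spike — is removed per pass and the track re-evaluated, which
    makes the filter deterministic and idempotent.  The first location of a
    track is never removed.  Animals with fewer than 3 locations pass through
    unchanged with a warning.

    Returns (kept locations, {animal_id: FilterReport}).
    """
    reports: dict[str, FilterReport] = {}
    kept_parts = []
    for animal, grp in locs.groupby("animal_id", sort=False):
        grp = grp.sort_values("time", kind="stable")
        report = FilterReport(n_input=len(grp))
        if len(grp) < 3:
            warnings.warn(f"sda_filter: animal {animal} has <3 locations; passthrough")
            kept_parts.append(grp)
            reports[animal] = report
            continue
        idx = grp.index.to_numpy()
        t = grp["time"].astype("int64").to_numpy() / 1e9
        lon = grp["lon"].to_numpy(dtype=float)
        lat = grp["lat"].to_numpy(dtype=float)
        alive = np.ones(len(grp), dtype=bool)

        while True:
            pos = np.nonzero(alive)[0]
            if len(pos) < 3:
                break
            tt, lo, la = t[pos], lon[pos], lat[pos]
            seg_speed = _implied_speeds_ms(tt, lo, la)
            # speed violators: interior points fast against both neighbours
            fast = (seg_speed[:-1] > vmax_ms) & (seg_speed[1:] > vmax_ms)
            if fast.any():
                worst = np.maximum(seg_speed[:-1], seg_speed[1:])
                j = int(np.nonzero(fast)[0][np.argmax(worst[fast])]) + 1
                alive[pos[j]] = False
                report.n_removed_speed += 1
                report.removed_indices.append(idx[pos[j]])
                continue
            # spikes: sharp angle with long legs on both sides
            seg_len = haversine_km(lo[:-1], la[:-1], lo[1:], la[1:])
            ang = turning_angle_deg(lo[:-2], la[:-2], lo[1:-1], la[1:-1],
                                    lo[2:], la[2:])
            spike = np.zeros(len(pos) - 2, dtype=bool)
            for ang_max, len_min in spike_rules:
                spike |= (ang < ang_max) & (seg_len[:-1] > len_min) \
                    & (seg_len[1:] > len_min)
            if spike.any():
                j = int(np.nonzero(spike)[0][np.argmin(ang[spike])]) + 1
                alive[pos[j]] = False
                report.n_removed_spike += 1
                report.removed_indices.append(idx[pos[j]])
                continue
            break

        kept_parts.append(grp.loc[idx[alive]])
        reports[animal] = report
    kept = pd.concat(kept_parts).sort_values(["animal_id", "time"], kind="stable")
    return kept.reset_index(drop=True), reports


def detect_haulouts(dry: pd.DataFrame, min_dry_minutes: float = 10.0) -> pd.DataFrame:
    """Haul-out intervals from a saltwater-switch record.

    ``dry`` has columns time (UTC) and dry (bool).  A haul-out starts once the
    sensor has been continuously dry for more than ``min_dry_minutes`` (the
    interval is anchored at the start of the dry spell) and ends at the first
    wet reading.  Returns a frame with columns start, end.
    """
    dry = dry.sort_values("time", kind="stable").reset_index(drop=True)
    events = []
    spell_start = None
    for row in dry.itertuples(index=False):
        if row.dry:
            if spell_start is None:
                spell_start = row.time
        else:
            if spell_start is not None:
                if (row.time - spell_start).total_seconds() > min_dry_minutes * 60:
                    events.append((spell_start, row.time))
                spell_start = None
    if spell_start is not None and len(dry):
        end = dry["time"].iloc[-1]
        if (end - spell_start).total_seconds() > min_dry_minutes * 60:
            events.append((spell_start, end))
    return pd.DataFrame(events, columns=["start", "end"])


# ---------------------------------------------------------------------------
# CTCRW state-space model
# ---------------------------------------------------------------------------


def _ctcrw_step(beta, sigma2, dt):
    """Transition (a, b) and process covariance for one coordinate.

    State [position, velocity]; x' = x + v (1-e^{-b dt})/b, v' = v e^{-b dt}.
    Returns (phi_xv, phi_vv, q_xx, q_xv, q_vv).
    """
    if dt <= 0:
        return 0.0, 1.0, 0.0, 0.0, 0.0
    a = np.exp(-beta * dt)
    phi_xv = (1.0 - a) / beta
    q_vv = sigma2 * (1.0 - a * a) / (2.0 * beta)
    q_xv = sigma2 * (1.0 - a) ** 2 / (2.0 * beta**2)
    q_xx = sigma2 / beta**2 * (dt - 2.0 * (1.0 - a) / beta + (1.0 - a * a) / (2.0 * beta))
    return phi_xv, a, q_xx, q_xv, q_vv


def _overlap_seconds(t0, t1, intervals):
    """Total overlap of [t0, t1] with a list of (start, end) seconds."""
    total = 0.0
    for s, e in intervals:
        total += max(0.0, min(t1, e) - max(t0, s))
    return total


class _Filter:
    """Kalman filter + RTS smoother for one coordinate over a merged grid."""

    def __init__(self, times_s, obs, obs_var, beta, sigma2, haulouts_s):
        self.t = times_s
        self.z = obs              # NaN where no observation
        self.r = obs_var
        n = len(times_s)
        self.xp = np.zeros((n, 2)); self.Pp = np.zeros((n, 3))   # predicted
        self.xf = np.zeros((n, 2)); self.Pf = np.zeros((n, 3))   # filtered
        self.steps = []
        self.loglik = 0.0
        # initial: diffuse
        first = np.nanargmin(np.where(np.isnan(obs), np.inf, times_s)) if np.any(~np.isnan(obs)) else 0
        x = np.array([obs[first] if not np.isnan(obs[first]) else 0.0, 0.0])
        P = np.array([1e4, 0.0, 1e2])  # (Pxx, Pxv, Pvv)
        for k in range(n):
            if k > 0:
                dt = self.t[k] - self.t[k - 1]
                moving = dt - _overlap_seconds(self.t[k - 1], self.t[k], haulouts_s)
                dt_eff = max(moving, 0.0) / 3600.0   # hours
                if dt <= 1e-9:
                    # duplicate timestamp: carry the full state unchanged
                    self.steps.append("dup")
                elif dt_eff <= 1e-12:
                    # movement frozen: position carried, velocity killed
                    x = np.array([x[0], 0.0])
                    P = np.array([P[0], 0.0, 0.0])
                    self.steps.append(None)
                else:
                    pxv, pvv, qxx, qxv, qvv = _ctcrw_step(beta, sigma2, dt_eff)
                    x_new = np.array([x[0] + pxv * x[1], pvv * x[1]])
                    Pxx = P[0] + 2 * pxv * P[1] + pxv**2 * P[2] + qxx
                    Pxv = pvv * (P[1] + pxv * P[2]) + qxv
                    Pvv = pvv**2 * P[2] + qvv
                    self.steps.append((pxv, pvv))
                    x, P = x_new, np.array([Pxx, Pxv, Pvv])
            self.xp[k], self.Pp[k] = x, P
            if not np.isnan(self.z[k]):
                S = max(P[0] + self.r[k], 1e-300)
                v = self.z[k] - x[0]
                self.loglik += -0.5 * (np.log(2 * np.pi * S) + v * v / S)
                kx = P[0] / S
                kv = P[1] / S
                x = np.array([x[0] + kx * v, x[1] + kv * v])
                # Joseph-form update keeps P positive semi-definite under
                # extreme measurement/process variance ratios
                r_k = self.r[k]
                a0 = 1.0 - kx
                Pxx = a0 * a0 * P[0] + kx * kx * r_k
                Pxv = a0 * (P[1] - kv * P[0]) + kx * kv * r_k
                Pvv = P[2] - 2 * kv * P[1] + kv * kv * P[0] + kv * kv * r_k
                P = np.array([Pxx, Pxv, max(Pvv, 0.0)])
            self.xf[k], self.Pf[k] = x, P

    def smooth(self):
        n = len(self.t)
        xs = self.xf.copy()
        Ps = self.Pf.copy()
        for k in range(n - 2, -1, -1):
            step = self.steps[k]
            Pf = self.Pf[k]
            Pp = self.Pp[k + 1]
            if step == "dup":
                xs[k] = xs[k + 1]
                Ps[k] = Ps[k + 1]
                continue
            if step is None:
                # frozen: smoothed position equals filtered (carried) position
                xs[k] = np.array([xs[k + 1][0], self.xf[k][1]])
                continue
            pxv, pvv = step
            # J = Pf Phi' Pp^{-1}
            Phi = np.array([[1.0, pxv], [0.0, pvv]])
            Pfm = np.array([[Pf[0], Pf[1]], [Pf[1], Pf[2]]])
            Ppm = np.array([[Pp[0], Pp[1]], [Pp[1], Pp[2]]])
            try:
                J = Pfm @ Phi.T @ np.linalg.inv(Ppm + 1e-12 * np.eye(2))
            except np.linalg.LinAlgError:  # pragma: no cover
                J = np.zeros((2, 2))
            xs[k] = self.xf[k] + J @ (xs[k + 1] - self.xp[k + 1])
            Psm = Pfm + J @ (np.array([[Ps[k + 1][0], Ps[k + 1][1]],
                                       [Ps[k + 1][1], Ps[k + 1][2]]]) - Ppm) @ J.T
            Ps[k] = np.array([Psm[0, 0], Psm[0, 1], Psm[1, 1]])
        return xs, Ps


@dataclass
class TrackModel:
    """Fitted CTCRW for one animal; geolocates any in-span timestamp."""

    animal_id: str
    beta: float                 # velocity autocorrelation decay, 1/hour
    sigma: float                # velocity noise scale, km/hour^1.5
    plane: LocalPlane
    times_s: np.ndarray         # observation epoch seconds
    obs_x: np.ndarray
    obs_y: np.ndarray
    obs_var: np.ndarray         # measurement variance per obs, km^2
    haulouts_s: list            # (start, end) epoch seconds
    loglik: float
    slack_s: float = 21_600.0   # +/- 6 h prediction slack

    @property
    def span(self):
        return self.times_s[0], self.times_s[-1]


def _neg_loglik(params, times_s, zx, zy, obs_var, haulouts_s, r_scale_free):
    log_beta, log_sigma = params[0], params[1]
    beta = np.exp(log_beta)
    sigma2 = np.exp(2 * log_sigma)
    scale = np.exp(2 * params[2]) if r_scale_free else 1.0
    fx = _Filter(times_s, zx, obs_var * scale, beta, sigma2, haulouts_s)
    fy = _Filter(times_s, zy, obs_var * scale, beta, sigma2, haulouts_s)
    ll = fx.loglik + fy.loglik
    if not np.isfinite(ll):
        return 1e12
    return -ll


def fit_track(locs: pd.DataFrame, haulouts: pd.DataFrame | None = None,
              class_sd_km: dict | None = None, fit_error_scale: bool = True,
              maxiter: int = 200) -> TrackModel:
    """Fit the CTCRW to one animal's SDA-filtered locations.

    ``locs`` holds one animal's rows (animal_id, time, lon, lat, loc_class);
    ``haulouts`` optional (start, end) intervals during which the process
    variance is zeroed and velocity frozen at 0.  Measurement SDs come from
    the per-class table, with an optional fitted common scale.  Parameters
    (beta, sigma) are estimated by maximum likelihood.
    """
    if locs["animal_id"].nunique() != 1:
        raise DataError("fit_track expects a single animal's locations")
    locs = locs.sort_values("time", kind="stable")
    sds = class_sd_km or DEFAULT_CLASS_SD_KM
    t = locs["time"].astype("int64").to_numpy() / 1e9
    plane = LocalPlane(float(locs["lon"].median()), float(locs["lat"].median()))
    zx, zy = plane.to_xy(locs["lon"].to_numpy(), locs["lat"].to_numpy())
    obs_var = np.array([sds[str(c)] ** 2 for c in locs["loc_class"]])
    ho = []
    if haulouts is not None and len(haulouts):
        ho = [(s.value / 1e9, e.value / 1e9)
              for s, e in zip(haulouts["start"], haulouts["end"])]

    span_h = max((t[-1] - t[0]) / 3600.0, 1.0)
    sig0 = max(np.std(np.diff(zx, prepend=zx[0])) + np.std(np.diff(zy, prepend=zy[0])), 1e-3)
    x0 = [np.log(1.0), np.log(sig0)]
    bounds = [(-12.0, 4.0), (-12.0, 6.0)]
    if fit_error_scale:
        x0.append(0.0)
        bounds.append((-10.0, 3.0))
    res = minimize(_neg_loglik, x0, args=(t, zx, zy, obs_var, ho, fit_error_scale),
                   method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "ftol": 1e-9})
    if not np.isfinite(res.fun):
        raise FitError("fit_track: likelihood not finite", last_objective=res.fun)
    beta = float(np.exp(res.x[0]))
    sigma = float(np.exp(res.x[1]))
    scale = float(np.exp(2 * res.x[2])) if fit_error_scale else 1.0
    return TrackModel(animal_id=str(locs["animal_id"].iloc[0]), beta=beta, sigma=sigma,
                      plane=plane, times_s=t, obs_x=zx, obs_y=zy,
                      obs_var=obs_var * scale, haulouts_s=ho, loglik=-float(res.fun))


def locate(model: TrackModel, times) -> pd.DataFrame:
    """Smoothed (lon, lat) point estimates at the requested timestamps.

    Raises :class:`DataError` for any time outside the model span plus slack.
    Returns a frame (time, lon, lat) in input order.
    """
    times = pd.DatetimeIndex(pd.to_datetime(times, utc=True))
    tq = times.asi8 / 1e9
    lo, hi = model.span
    if np.any(tq < lo - model.slack_s) or np.any(tq > hi + model.slack_s):
        raise DataError("locate: requested time outside model span + slack")
    # merged grid: observations plus query times
    t_all = np.concatenate([model.times_s, tq])
    z_x = np.concatenate([model.obs_x, np.full(len(tq), np.nan)])
    z_y = np.concatenate([model.obs_y, np.full(len(tq), np.nan)])
    r = np.concatenate([model.obs_var, np.full(len(tq), np.nan)])
    order = np.argsort(t_all, kind="stable")
    inv = np.empty_like(order); inv[order] = np.arange(len(order))
    sigma2 = model.sigma**2
    fx = _Filter(t_all[order], z_x[order], r[order], model.beta, sigma2, model.haulouts_s)
    fy = _Filter(t_all[order], z_y[order], r[order], model.beta, sigma2, model.haulouts_s)
    sx, _ = fx.smooth()
    sy, _ = fy.smooth()
    qpos = inv[len(model.times_s):]
    lon, lat = model.plane.to_lonlat(sx[qpos, 0], sy[qpos, 0])
    return pd.DataFrame({"time": times, "lon": lon, "lat": lat})
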