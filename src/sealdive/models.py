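"""The statistical layer: additive mixed models with BIC selection.

The workhorse is a penalized-regression-spline additive mixed model (AMM):

    y = F alpha + sum_j B_j b_j + Z u + e,
    b_j ~ N(0, sigma^2 / lambda_j I),  u ~ N(0, sigma_b^2) per animal,
    e   ~ AR(1) within animal with parameter phi,

fitted by direct Gaussian (restricted) maximum likelihood: smoothing
parameters, the AR(1) coefficient and the random-intercept variance ratio are
chosen by REML, and the model is re-evaluated at those values under ML for
BIC comparison across fixed-effect structures.  Smooths are cubic B-splines
with a second-order difference penalty (P-splines); each smooth's penalty
null space contributes a fixed linear column and the penalized part is
transformed to an identity penalty.  Linear mixed models (the monthly diel
analyses) are the special case with no smooth terms; plain GAMs (the wind-lag
suite) the special case with no grouping.

BIC uses n = number of observations and df = effective degrees of freedom of
the mean structure plus the variance-parameter count; BIC weights are
exp(-dBIC/2), normalized over the candidate set.

The Poisson daily-count model is a penalized Poisson additive model (PIRLS)
without AR(1) or random intercept — combining them is not supported and the
limitation is logged.  The dive-type model is multinomial logistic via
statsmodels MNLogit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import gammaln

from .errors import DataError, FitError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmoothTerm:
    """One penalized spline term; ``by`` fits a separate smooth per level."""

    var: str
    by: str | None = None
    k: int = 10


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model structure."""

    response: str
    smooths: tuple = ()
    linear: tuple = ()
    group: str | None = "animal_id"
    ar1: bool = True
    family: str = "gaussian"
    time_col: str = "date"
    ar1_unit_days: float = 1.0
    name: str = ""

    def label(self) -> str:
        if self.name:
            return self.name
        parts = [f"f({s.var},by={s.by})" if s.by else f"f({s.var})" for s in self.smooths]
        parts += list(self.linear)
        return " + ".join(parts) if parts else "null"


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def bspline_matrix(x, knots_interior, degree=3):
    """Cubic B-spline design matrix with the given interior knots."""
    from scipy.interpolate import BSpline
    t = np.concatenate([[knots_interior[0]] * (degree + 1), knots_interior[1:-1],
                        [knots_interior[-1]] * (degree + 1)])
    n_basis = len(t) - degree - 1
    X = np.empty((len(x), n_basis))
    xc = np.clip(x, knots_interior[0], knots_interior[-1])
    for i in range(n_basis):
        c = np.zeros(n_basis)
        c[i] = 1.0
        X[:, i] = BSpline(t, c, degree)(xc)
    return X


def _is_datetime(col: pd.Series) -> bool:
    return pd.api.types.is_datetime64_any_dtype(col)


def _naive(col: pd.Series) -> pd.Series:
    """Strip any timezone (converting to UTC first) so date arithmetic is
    uniform regardless of how the caller localized their frames."""
    if _is_datetime(col) and getattr(col.dt, "tz", None) is not None:
        return col.dt.tz_convert("UTC").dt.tz_localize(None)
    return col


def _numeric(col: pd.Series) -> np.ndarray:
    if _is_datetime(col):
        col = _naive(col)
        t0 = col.min()
        return (col - t0).dt.total_seconds().to_numpy() / 86_400.0
    return col.to_numpy(dtype=float)


@dataclass
class _SmoothBlock:
    term: SmoothTerm
    by_level: object          # None for plain smooths
    knots: np.ndarray
    transform: np.ndarray     # k x q map to identity-penalty coordinates
    col_means: np.ndarray     # centering means over active rows
    x_mean: float             # for the fixed null-space column
    x_ref: object             # origin for datetime conversion
    fixed_cols: slice = None
    pen_cols: slice = None


class _Design:
    """Fixed matrix F, penalized blocks R_j, and everything needed to
    rebuild prediction rows."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        n = len(data)
        self.spec = spec
        self.n = n
        F_cols, F_names = [np.ones(n)], ["(intercept)"]
        # linear terms
        self.linear_info = []
        for name in spec.linear:
            col = data[name]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                cats = sorted(pd.unique(col.astype(str)))
                self.linear_info.append((name, "cat", cats))
                for c in cats[1:]:
                    F_cols.append((col.astype(str) == c).to_numpy(dtype=float))
                    F_names.append(f"{name}[{c}]")
            else:
                self.linear_info.append((name, "num", None))
                F_cols.append(col.to_numpy(dtype=float))
                F_names.append(name)
        # smooths
        self.blocks: list[_SmoothBlock] = []
        R_blocks = []
        for term in spec.smooths:
            levels = [None]
            if term.by is not None:
                levels = sorted(pd.unique(data[term.by].astype(str)))
            for lev in levels:
                if lev is None:
                    active = np.ones(n, dtype=bool)
                else:
                    active = (data[term.by].astype(str) == lev).to_numpy()
                col = _naive(data[term.var])
                x_ref = col.min() if _is_datetime(col) else None
                x = _numeric(col)
                xa = x[active]
                if xa.max() == xa.min():
                    raise DataError(f"smooth '{term.var}': no variation within level {lev}")
                knots = np.linspace(xa.min(), xa.max(), term.k - 2)
                B = bspline_matrix(x, knots)
                B[~active] = 0.0
                col_means = B[active].mean(axis=0)
                Bc = B.copy()
                Bc[active] -= col_means
                # second-order difference penalty, identity reparametrization
                D = np.diff(np.eye(B.shape[1]), n=2, axis=0)
                S = D.T @ D
                w, U = np.linalg.eigh(S)
                pos = w > 1e-8
                transform = U[:, pos] / np.sqrt(w[pos])
                R = Bc @ transform
                x_mean = xa.mean()
                fx = np.zeros(n)
                fx[active] = xa - x_mean
                F_cols.append(fx)
                F_names.append(f"f({term.var}){'' if lev is None else f'[{lev}]'}:lin")
                blk = _SmoothBlock(term=term, by_level=lev, knots=knots,
                                   transform=transform, col_means=col_means,
                                   x_mean=x_mean, x_ref=x_ref)
                blk.fixed_cols = len(F_cols) - 1
                R_blocks.append(R)
                self.blocks.append(blk)
        self.F = np.column_stack(F_cols)
        self.F_names = F_names
        self.R_blocks = R_blocks
        self.C = np.column_stack([self.F] + R_blocks) if R_blocks else self.F
        self.p = self.F.shape[1]
        self.q_sizes = [R.shape[1] for R in R_blocks]

    def prediction_rows(self, newdata: pd.DataFrame) -> np.ndarray:
        """Design rows [F R] for new data, matching the fitted columns."""
        m = len(newdata)
        cols = [np.ones(m)]
        for name, kind, cats in self.linear_info:
            col = newdata[name]
            if kind == "cat":
                for c in cats[1:]:
                    cols.append((col.astype(str) == c).to_numpy(dtype=float))
            else:
                cols.append(col.to_numpy(dtype=float))
        pen_parts = []
        for blk in self.blocks:
            term = blk.term
            if blk.by_level is None:
                active = np.ones(m, dtype=bool)
            else:
                active = (newdata[term.by].astype(str) == blk.by_level).to_numpy()
            col = _naive(newdata[term.var])
            if blk.x_ref is not None:
                x = (col - blk.x_ref).dt.total_seconds().to_numpy() / 86_400.0
            else:
                x = col.to_numpy(dtype=float)
            fx = np.zeros(m)
            fx[active] = x[active] - blk.x_mean
            cols.append(fx)
            B = bspline_matrix(x, blk.knots)
            B[~active] = 0.0
            Bc = B.copy()
            Bc[active] -= blk.col_means
            pen_parts.append(Bc @ blk.transform)
        return np.column_stack(cols + pen_parts) if pen_parts else np.column_stack(cols)


# ---------------------------------------------------------------------------
# Gaussian AMM fitting
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """A fitted additive mixed model with everything BIC selection needs."""

    spec: ModelSpec
    coef: np.ndarray
    cov_unscaled: np.ndarray      # A^{-1}; posterior cov is sigma2 * A^{-1}
    sigma2: float
    phi: float
    re_ratio: float               # sigma_b^2 / sigma^2
    lambdas: np.ndarray
    edf: float
    df_model: float               # edf + variance-parameter count
    loglik_ml: float
    n: int
    bic: float
    design: _Design
    re_degenerate: bool = False
    loglik_reml: float | None = None

    @property
    def re_var(self) -> float:
        return self.re_ratio * self.sigma2

    def predict(self, newdata: pd.DataFrame, se: bool = True) -> pd.DataFrame:
        """Population-level prediction (random effects at 0) with pointwise SE."""
        Crows = self.design.prediction_rows(newdata)
        fit = Crows @ self.coef
        out = pd.DataFrame({"fit": fit}, index=newdata.index)
        if se:
            var = np.einsum("ij,jk,ik->i", Crows, self.cov_unscaled, Crows) * self.sigma2
            out["se"] = np.sqrt(np.maximum(var, 0.0))
        return out


def _group_whiteners(codes, times_days, phi, r, unit_days):
    """Cholesky factor per group of corr = phi^|dt/unit| + r."""
    Ls = []
    logdet = 0.0
    for g in np.unique(codes):
        idx = np.nonzero(codes == g)[0]
        t = times_days[idx]
        if phi != 0.0:
            V = phi ** (np.abs(t[:, None] - t[None, :]) / unit_days)
        else:
            V = np.eye(len(idx))
        if r != 0.0:
            V = V + r
        L = np.linalg.cholesky(V)
        logdet += 2.0 * np.sum(np.log(np.diag(L)))
        Ls.append((idx, L))
    return Ls, logdet


def _penalized_fit(C, y, p, q_sizes, lambdas):
    """Solve the penalized normal equations; return pieces of the likelihood."""
    CtC = C.T @ C
    A = CtC.copy()
    Cty = C.T @ y
    pos = p
    for q, lam in zip(q_sizes, lambdas):
        A[pos:pos + q, pos:pos + q] += lam * np.eye(q)
        pos += q
    try:
        cf = cho_factor(A + 1e-10 * np.eye(A.shape[0]))
    except np.linalg.LinAlgError:
        raise FitError("penalized normal equations not positive definite")
    delta = cho_solve(cf, Cty)
    resid = y - C @ delta
    pen = 0.0
    pos = p
    for q, lam in zip(q_sizes, lambdas):
        pen += lam * float(delta[pos:pos + q] @ delta[pos:pos + q])
        pos += q
    rssp = float(resid @ resid) + pen
    # log|Lambda + R'R| - log|Lambda| for the ML determinant term
    logdet_pen = 0.0
    if q_sizes:
        qtot = sum(q_sizes)
        Rblock = CtC[p:, p:].copy()
        pos = 0
        loglam = 0.0
        for q, lam in zip(q_sizes, lambdas):
            Rblock[pos:pos + q, pos:pos + q] += lam * np.eye(q)
            loglam += q * np.log(lam)
            pos += q
        sign, ld = np.linalg.slogdet(Rblock)
        logdet_pen = ld - loglam
    sign, logdet_A = np.linalg.slogdet(A)
    Ainv = cho_solve(cf, np.eye(A.shape[0]))
    edf = float(np.trace(Ainv @ CtC))
    return delta, rssp, logdet_pen, logdet_A, Ainv, edf


def fit_amm(data: pd.DataFrame, spec: ModelSpec, criterion: str = "reml",
            maxiter: int = 300) -> ModelFit:
    """Fit a Gaussian additive mixed model.

    Variance/smoothing parameters maximize the REML criterion (or ML when
    ``criterion='ml'``); the reported ``loglik_ml`` and BIC always come from
    an ML evaluation at those parameters, so BIC is comparable across
    fixed-effect structures.
    """
    if spec.family == "poisson":
        return fit_poisson_pam(data, spec)
    used = [spec.response] + [s.var for s in spec.smooths] + list(spec.linear)
    used += [s.by for s in spec.smooths if s.by]
    if spec.group:
        used.append(spec.group)
    if spec.ar1:
        used.append(spec.time_col)
    data = data.dropna(subset=[c for c in dict.fromkeys(used)]).reset_index(drop=True)
    n = len(data)
    if n < 5:
        raise DataError("fit_amm: too few complete observations")
    y = data[spec.response].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise DataError("fit_amm: response has zero variance")
    des = _Design(data, spec)
    C = des.C
    p, q_sizes = des.p, des.q_sizes

    if spec.group:
        codes = pd.Categorical(data[spec.group].astype(str)).codes
    else:
        codes = np.zeros(n, dtype=int)
    times = _numeric(data[spec.time_col]) if spec.ar1 else np.arange(n, dtype=float)

    n_lam = len(q_sizes)
    use_phi = bool(spec.ar1)
    use_r = spec.group is not None
    theta0 = [2.0] * n_lam + ([0.5] if use_phi else []) + ([-1.0] if use_r else [])

    def unpack(theta):
        lam = np.exp(np.clip(theta[:n_lam], -20, 20))
        i = n_lam
        # AR(1) persistence is constrained to [0, 0.99): residual dependence
        # is modelled as decay, never oscillation
        phi = abs(np.tanh(theta[i])) * 0.99 if use_phi else 0.0
        if use_phi:
            i += 1
        r = np.exp(np.clip(theta[i], -20, 8)) if use_r else 0.0
        return lam, phi, r

    def neg2(theta, restricted):
        lam, phi, r = unpack(theta)
        try:
            if phi != 0.0 or r != 0.0:
                Ls, logdet_V = _group_whiteners(codes, times, phi, r, spec.ar1_unit_days)
                yw = y.copy().astype(float)
                Cw = C.copy()
                for idx, L in Ls:
                    yw[idx] = solve_triangular(L, y[idx], lower=True)
                    Cw[idx] = solve_triangular(L, C[idx], lower=True)
            else:
                yw, Cw, logdet_V = y, C, 0.0
            delta, rssp, logdet_pen, logdet_A, Ainv, edf = _penalized_fit(
                Cw, yw, p, q_sizes, lam)
        except (FitError, np.linalg.LinAlgError):
            return 1e12, None
        if restricted:
            dof = n - p
            sig2 = rssp / dof
            val = dof * np.log(2 * np.pi * sig2) + dof + logdet_V + logdet_A \
                - sum(q * np.log(l) for q, l in zip(q_sizes, lam))
        else:
            sig2 = rssp / n
            val = n * np.log(2 * np.pi * sig2) + n + logdet_V + logdet_pen
        if not np.isfinite(val):
            return 1e12, None
        return val, (delta, rssp, Ainv, edf, sig2, logdet_V, logdet_pen)

    restricted = criterion == "reml"
    if len(theta0):
        res = minimize(lambda th: neg2(th, restricted)[0], np.array(theta0),
                       method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-4})
        theta = res.x
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            raise FitError("fit_amm: optimizer failed", last_objective=res.fun)
    else:
        theta = np.array([])
    lam, phi, r = unpack(theta)
    val_reml, _ = neg2(theta, True)
    val_ml, pieces = neg2(theta, False)
    if pieces is None:
        raise FitError("fit_amm: final evaluation failed", last_objective=val_ml)
    delta, rssp, Ainv, edf, sig2, logdet_V, logdet_pen = pieces
    n_var = 1 + (1 if use_phi else 0) + (1 if use_r else 0)
    df_model = edf + n_var
    loglik_ml = -0.5 * val_ml
    bic = val_ml + df_model * np.log(n)
    return ModelFit(spec=spec, coef=delta, cov_unscaled=Ainv, sigma2=sig2,
                    phi=phi, re_ratio=r, lambdas=lam, edf=edf, df_model=df_model,
                    loglik_ml=loglik_ml, n=n, bic=bic, design=des,
                    re_degenerate=bool(use_r and r < 1e-6),
                    loglik_reml=-0.5 * val_reml)


def fit_seasonal_gamm(daily: pd.DataFrame, spec: ModelSpec, **kw) -> ModelFit:
    """Seasonal GAMM on complete daily records (thin wrapper over fit_amm).

    ``daily`` must carry a boolean ``complete`` column; only complete days
    enter the fit, per the four-summaries-per-day rule.
    """
    if "complete" in daily.columns:
        daily = daily[daily["complete"]]
    return fit_amm(daily, spec, **kw)


def fit_diel_lme(data: pd.DataFrame, spec: ModelSpec, **kw) -> ModelFit:
    """Monthly linear mixed model for diel effects (no smooth terms).

    The caller subsets to one month and supplies log-transformed responses
    where appropriate.  Raises if only one diel level is present when the
    spec includes a diel term.
    """
    if any(t == "period" or t.startswith("period") for t in spec.linear):
        if data["period"].nunique() < 2:
            raise DataError("fit_diel_lme: only one diel level present")
    if spec.smooths:
        raise DataError("fit_diel_lme: smooth terms do not belong in an LME spec")
    return fit_amm(data, spec, **kw)


# ---------------------------------------------------------------------------
# Poisson penalized additive model (no AR1 / random intercept)
# ---------------------------------------------------------------------------


def fit_poisson_pam(data: pd.DataFrame, spec: ModelSpec, maxiter: int = 100) -> ModelFit:
    """Penalized Poisson additive model fitted by PIRLS.

    AR(1) and the animal random intercept are not combined with the Poisson
    family; that limitation is logged, matching the model actually used for
    daily dive counts.
    """
    log.info("fit_poisson_pam: AR(1)/random intercept not supported with poisson family")
    used = [spec.response] + [s.var for s in spec.smooths] + list(spec.linear)
    used += [s.by for s in spec.smooths if s.by]
    data = data.dropna(subset=[c for c in dict.fromkeys(used)]).reset_index(drop=True)
    y = data[spec.response].to_numpy(dtype=float)
    if np.any(y < 0):
        raise DataError("poisson response must be non-negative")
    des = _Design(data, spec)
    C, p, q_sizes = des.C, des.p, des.q_sizes
    n = len(y)

    def pirls(lam):
        eta = np.log(np.maximum(y, 0.5))
        delta = None
        for _ in range(maxiter):
            mu = np.exp(np.clip(eta, -30, 30))
            w = np.sqrt(mu)
            z = eta + (y - mu) / mu
            Cw = C * w[:, None]
            zw = z * w
            delta_new, rssp, _, _, Ainv, edf = _penalized_fit(Cw, zw, p, q_sizes, lam)
            eta_new = C @ delta_new
            if delta is not None and np.max(np.abs(eta_new - eta)) < 1e-8:
                delta = delta_new
                eta = eta_new
                break
            delta, eta = delta_new, eta_new
        mu = np.exp(np.clip(eta, -30, 30))
        yl = np.zeros_like(y)
        posy = y > 0
        yl[posy] = y[posy] * np.log(y[posy] / mu[posy])
        dev = 2.0 * np.sum(yl - (y - mu))
        return delta, mu, dev, Ainv, edf

    def gcv(log_lam):
        lam = np.exp(np.clip(log_lam, -20, 20))
        try:
            _, _, dev, _, edf = pirls(lam)
        except (FitError, np.linalg.LinAlgError):
            return 1e12
        denom = max(n - edf, 1.0)
        return n * dev / denom**2

    n_lam = len(q_sizes)
    if n_lam:
        res = minimize(gcv, np.full(n_lam, 2.0), method="Nelder-Mead",
                       options={"maxiter": 100, "xatol": 1e-2, "fatol": 1e-3})
        lam = np.exp(np.clip(res.x, -20, 20))
    else:
        lam = np.array([])
    delta, mu, dev, Ainv, edf = pirls(lam)
    loglik = float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
    df_model = edf
    bic = -2.0 * loglik + df_model * np.log(n)
    return ModelFit(spec=spec, coef=delta, cov_unscaled=Ainv, sigma2=1.0,
                    phi=0.0, re_ratio=0.0, lambdas=lam, edf=edf, df_model=df_model,
                    loglik_ml=loglik, n=n, bic=bic, design=des)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def bic_weights(bics) -> np.ndarray:
    """BIC weights exp(-dBIC/2) normalized over the candidate set."""
    b = np.asarray(bics, dtype=float)
    d = b - b.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def select_models(data: pd.DataFrame, specs, fitter=fit_amm, **kw) -> pd.DataFrame:
    """Fit every candidate on the identical observation set and rank by BIC.

    Returns a table (model, bic, dbic, bicw, edf, n) sorted by ascending BIC;
    weights are normalized over the full candidate set before any display
    filtering.  Raises when candidates would be fitted on differing row sets.
    """
    specs = list(specs)
    if len(specs) < 2:
        raise DataError("select_models: need at least 2 candidates")
    masks = []
    for spec in specs:
        used = [spec.response] + [s.var for s in spec.smooths] + list(spec.linear)
        used += [s.by for s in spec.smooths if s.by]
        masks.append(data[list(dict.fromkeys(used))].notna().all(axis=1))
    for m in masks[1:]:
        if not m.equals(masks[0]):
            raise DataError("select_models: candidates see different observation rows")
    rows = []
    fits = []
    for spec in specs:
        fit = fitter(data[masks[0]], spec, **kw)
        fits.append(fit)
        rows.append({"model": spec.label(), "bic": fit.bic, "edf": fit.edf, "n": fit.n})
    table = pd.DataFrame(rows)
    table["dbic"] = table["bic"] - table["bic"].min()
    table["bicw"] = bic_weights(table["bic"].to_numpy())
    table = table.sort_values("bic", kind="stable").reset_index(drop=True)
    table.attrs["fits"] = fits
    return table


# ---------------------------------------------------------------------------
# Multinomial dive-type model
# ---------------------------------------------------------------------------


def _mn_design(data: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    n = len(data)
    cols, names = [np.ones(n)], ["(intercept)"]
    for term in terms:
        if "*" in term:
            a, b = term.split("*")
            da = pd.get_dummies(data[a].astype(str), prefix=a, drop_first=True)
            db = pd.get_dummies(data[b].astype(str), prefix=b, drop_first=True)
            for ca in da.columns:
                cols.append(da[ca].to_numpy(dtype=float)); names.append(ca)
            for cb in db.columns:
                cols.append(db[cb].to_numpy(dtype=float)); names.append(cb)
            for ca in da.columns:
                for cb in db.columns:
                    cols.append((da[ca] * db[cb]).to_numpy(dtype=float))
                    names.append(f"{ca}:{cb}")
        else:
            d = pd.get_dummies(data[term].astype(str), prefix=term, drop_first=True)
            for c in d.columns:
                cols.append(d[c].to_numpy(dtype=float)); names.append(c)
    X = np.column_stack(cols)
    # drop exactly collinear duplicates (e.g. main effects repeated across terms)
    keep, seen = [], set()
    for j, nm in enumerate(names):
        if nm not in seen:
            seen.add(nm); keep.append(j)
    return X[:, keep], [names[j] for j in keep]


DIVE_TYPE_CANDIDATES = ((), ("month",), ("month", "year"), ("month*year",),
                        ("month*year", "age"))


def fit_dive_type_multinomial(data: pd.DataFrame, candidates=DIVE_TYPE_CANDIDATES):
    """Multinomial dive-type model (coastal/benthic/pelagic ~ month, year, age).

    Fits every candidate term structure by maximum likelihood (ridge-penalized
    fallback, flagged, when a category is unobserved in some month and the fit
    separates), selects by BIC, and returns (selection table, best-fit result,
    per-month predicted probabilities for the best model).
    """
    import statsmodels.api as sm

    cats = pd.Categorical(data["dive_class"].astype(str))
    if len(cats.categories) < 2:
        raise DataError("dive-type model: need >= 2 observed categories")
    y = cats.codes
    rows, fitted = [], []
    for terms in candidates:
        X, names = _mn_design(data, terms)
        model = sm.MNLogit(y, X)
        flagged = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(method="lbfgs", maxiter=500, disp=False)
                if not np.isfinite(res.llf) or np.max(np.abs(res.params)) > 50:
                    raise ValueError("separation")
            except Exception:
                res = model.fit_regularized(method="l1", alpha=1e-4, disp=False,
                                            maxiter=500)
                flagged = True
        k = res.params.size
        bic = -2.0 * res.llf + k * np.log(len(y))
        label = "+".join(terms) if terms else "null"
        rows.append({"model": label, "bic": bic, "k": k, "flagged": flagged})
        fitted.append((terms, res, names))
    table = pd.DataFrame(rows)
    table["dbic"] = table["bic"] - table["bic"].min()
    table["bicw"] = bic_weights(table["bic"].to_numpy())
    order = table["bic"].to_numpy().argsort(kind="stable")
    best_terms, best_res, best_names = fitted[order[0]]
    # per-month predicted probabilities at the modal year/age
    grid = {"month": sorted(pd.unique(data["month"]))}
    for extra in ("year", "age"):
        if extra in data.columns:
            grid[extra] = [data[extra].mode().iloc[0]]
    gframe = pd.DataFrame([{k: v for k, v in zip(grid, combo)}
                           for combo in __import__("itertools").product(*grid.values())])
    # rebuild the design on train+grid so dummy columns align
    stacked = pd.concat([data[list(grid.keys())], gframe], ignore_index=True)
    Xall, _ = _mn_design(stacked, best_terms)
    probs = best_res.predict(Xall[len(data):])
    pframe = gframe.copy()
    for j, cat in enumerate(cats.categories):
        pframe[str(cat)] = probs[:, j]
    table = table.sort_values("bic", kind="stable").reset_index(drop=True)
    return table, best_res, pframe


# ---------------------------------------------------------------------------
# Wind-lag GAM suite
# ---------------------------------------------------------------------------


def wind_candidates(response: str, wind_col: str, year_col: str = "year",
                    date_smooth_k: int = 10, wind_k: int = 8):
    """Candidate structures mirroring the upwelling analysis: a by-year date
    smooth, plus nothing / a linear wind term / a wind smooth / a by-year
    wind smooth."""
    date_s = SmoothTerm("date", by=year_col, k=date_smooth_k)
    return [
        ModelSpec(response, smooths=(date_s,), group=None, ar1=False,
                  name="f(date,by=year)"),
        ModelSpec(response, smooths=(date_s,), linear=(wind_col,), group=None,
                  ar1=False, name=f"f(date,by=year)+{wind_col}"),
        ModelSpec(response, smooths=(date_s, SmoothTerm(wind_col, k=wind_k)),
                  group=None, ar1=False, name=f"f(date,by=year)+f({wind_col})"),
        ModelSpec(response, smooths=(date_s, SmoothTerm(wind_col, by=year_col, k=wind_k)),
                  group=None, ar1=False, name=f"f(date,by=year)+f({wind_col},by=year)"),
    ]


def fit_wind_gam(daily: pd.DataFrame, response: str, wind: pd.DataFrame,
                 lags=range(1, 8), sectors=("N", "NE")) -> dict:
    """Wind-lag model selection for one daily response.

    For every lag in 1..7 days and each wind sector, builds the lagged mean
    directional wind covariate, fits the candidate GAM structures, and selects
    the best (lag, structure) by BIC.  All-zero covariates drop their specs
    with a warning.  Returns {'table': full selection table, 'best_lag',
    'best_sector', 'best_model', 'baseline_bic'}.
    """
    from .envlink import wind_covariates

    daily = daily.dropna(subset=[response, "date"]).reset_index(drop=True)
    if "year" not in daily.columns:
        raise DataError("fit_wind_gam: daily frame needs a 'year' column")
    base_spec = wind_candidates(response, "wind_dummy")[0]
    base_fit = fit_amm(daily, base_spec)
    rows = [{"model": "f(date,by=year)", "lag_days": 0, "sector": "-",
             "bic": base_fit.bic, "edf": base_fit.edf}]
    for sector in sectors:
        for lag in lags:
            cov = wind_covariates(wind, daily["date"], lag, sector=sector)
            col = f"{sector}_lag{lag}"
            d = daily.copy()
            d[col] = cov["value"].to_numpy()
            if np.allclose(d[col], 0.0):
                warnings.warn(f"fit_wind_gam: covariate {col} all zero; specs dropped")
                continue
            for spec in wind_candidates(response, col)[1:]:
                fit = fit_amm(d, spec)
                rows.append({"model": spec.label(), "lag_days": lag, "sector": sector,
                             "bic": fit.bic, "edf": fit.edf})
    table = pd.DataFrame(rows)
    table["dbic"] = table["bic"] - table["bic"].min()
    table["bicw"] = bic_weights(table["bic"].to_numpy())
    table = table.sort_values("bic", kind="stable").reset_index(drop=True)
    best = table.iloc[0]
    return {"table": table, "best_lag": int(best["lag_days"]),
            "best_sector": best["sector"], "best_model": best["model"],
            "baseline_bic": float(base_fit.bic)}


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def estimate_ar1(x) -> float:
    """Lag-1 autocorrelation (the AR(1) coefficient estimator used in checks)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 0.0
    return float(x[1:] @ x[:-1] / denom)
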