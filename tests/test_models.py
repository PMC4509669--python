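import numpy as np
import pandas as pd
import pytest

from sealdive import models as M
from sealdive.errors import DataError


# ---------------------------------------------------------------------------
# BIC weights (closed form)
# ---------------------------------------------------------------------------


def test_bic_weights_closed_form():
    w = M.bic_weights([100.0, 102.0, 110.0])
    np.testing.assert_allclose(w, [0.72747516, 0.26762315, 0.00490169],
                               atol=1e-6)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_bic_weights_invariant_to_shift():
    np.testing.assert_allclose(M.bic_weights([0.0, 2.0, 10.0]),
                               M.bic_weights([100.0, 102.0, 110.0]), atol=1e-12)


# ---------------------------------------------------------------------------
# AMM engine
# ---------------------------------------------------------------------------


def _smooth_data(rng, n_per=120, n_animals=3, phi=0.0, re_sd=0.0, noise=1.0):
    frames = []
    for i in range(n_animals):
        x = np.linspace(0.0, 10.0, n_per)
        f = 8.0 * np.sin(x)
        e = np.empty(n_per)
        e[0] = rng.normal(0, noise)
        for k in range(1, n_per):
            e[k] = phi * e[k - 1] + rng.normal(0, noise * np.sqrt(1 - phi**2))
        frames.append(pd.DataFrame({
            "animal_id": f"S{i}", "x": x,
            "date": pd.date_range("2010-06-01", periods=n_per, freq="D"),
            "y": f + rng.normal(0, re_sd) + e}))
    return pd.concat(frames, ignore_index=True)


def test_amm_recovers_smooth_function(rng):
    data = _smooth_data(rng)
    spec = M.ModelSpec(response="y", smooths=(M.SmoothTerm("x", k=12),),
                       group="animal_id", ar1=False)
    fit = M.fit_amm(data, spec)
    grid = pd.DataFrame({"x": np.linspace(0.5, 9.5, 50)})
    pred = fit.predict(grid, se=True)
    rmse = float(np.sqrt(np.mean((pred["fit"].to_numpy()
                                  - 8.0 * np.sin(grid["x"].to_numpy())) ** 2)))
    assert rmse < 0.6
    assert (pred["se"] > 0).all()
    assert 4.0 < fit.edf < 20.0


def test_amm_estimates_ar1(rng):
    data = _smooth_data(rng, phi=0.6, n_per=250)
    spec = M.ModelSpec(response="y", smooths=(M.SmoothTerm("x", k=10),),
                       group="animal_id", ar1=True, time_col="date")
    fit = M.fit_amm(data, spec)
    assert fit.phi == pytest.approx(0.6, abs=0.15)


def test_amm_random_intercept_variance(rng):
    data = _smooth_data(rng, re_sd=3.0, n_animals=8, n_per=60)
    spec = M.ModelSpec(response="y", smooths=(M.SmoothTerm("x", k=10),),
                       group="animal_id", ar1=False)
    fit = M.fit_amm(data, spec)
    assert 1.0 < fit.re_var < 30.0
    assert not fit.re_degenerate


def test_amm_zero_variance_response_raises():
    data = pd.DataFrame({"animal_id": "A", "x": np.arange(30.0),
                         "date": pd.date_range("2010-01-01", periods=30),
                         "y": 5.0})
    spec = M.ModelSpec(response="y", smooths=(M.SmoothTerm("x"),))
    with pytest.raises(DataError, match="zero variance"):
        M.fit_amm(data, spec)


def test_amm_ml_vs_reml_consistent_bic(rng):
    data = _smooth_data(rng, n_animals=2, n_per=80)
    spec = M.ModelSpec(response="y", smooths=(M.SmoothTerm("x", k=10),),
                       group="animal_id", ar1=False)
    fit = M.fit_amm(data, spec, criterion="reml")
    # BIC is assembled from the ML evaluation
    assert fit.bic == pytest.approx(-2.0 * fit.loglik_ml
                                    + fit.df_model * np.log(fit.n), abs=1e-8)


def test_select_models_ranks_and_guards(rng):
    data = _smooth_data(rng, n_animals=2, n_per=100)
    data["z"] = rng.normal(0, 1, len(data))       # irrelevant covariate
    s0 = M.ModelSpec(response="y", smooths=(M.SmoothTerm("x", k=10),),
                     group="animal_id", ar1=False, name="f(x)")
    s1 = M.ModelSpec(response="y", smooths=(M.SmoothTerm("x", k=10),),
                     linear=("z",), group="animal_id", ar1=False, name="f(x)+z")
    table = M.select_models(data, [s0, s1])
    assert table["model"].iloc[0] == "f(x)"       # noise covariate penalized
    assert table["bicw"].sum() == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(DataError, match="at least 2"):
        M.select_models(data, [s0])
    data2 = data.copy()
    data2.loc[data2.index[:5], "z"] = np.nan
    with pytest.raises(DataError, match="different observation rows"):
        M.select_models(data2, [s0, s1])


def test_diel_lme_requires_both_levels(rng):
    df = pd.DataFrame({"animal_id": "A", "period": "day",
                       "date": pd.date_range("2010-09-01", periods=30),
                       "y": rng.normal(50, 5, 30)})
    spec = M.ModelSpec(response="y", linear=("period",), group="animal_id",
                       ar1=False)
    with pytest.raises(DataError, match="one diel level"):
        M.fit_diel_lme(df, spec)


def test_diel_lme_detects_offset(rng):
    rows = []
    for i in range(4):
        for day in range(40):
            for j, period in enumerate(("day", "night")):
                rows.append({"animal_id": f"S{i}", "period": period,
                             "t": day + 0.25 + 0.5 * j,
                             "y": 50.0 + (6.0 if period == "night" else 0.0)
                             + rng.normal(0, 4)})
    df = pd.DataFrame(rows)
    with_diel = M.ModelSpec(response="y", linear=("period",), group="animal_id",
                            ar1=True, time_col="t", name="period")
    without = M.ModelSpec(response="y", group="animal_id", ar1=True,
                          time_col="t", name="null")
    t_with = M.fit_diel_lme(df, with_diel)
    t_null = M.fit_amm(df, without)
    assert t_with.bic < t_null.bic
    j = t_with.design.F_names.index("period[night]")
    assert t_with.coef[j] == pytest.approx(6.0, abs=1.0)


# ---------------------------------------------------------------------------
# Poisson PAM
# ---------------------------------------------------------------------------


def test_poisson_pam_recovers_rate_curve(rng):
    n = 300
    x = np.linspace(0, 10, n)
    mu = np.exp(2.0 + 0.8 * np.sin(x))
    y = rng.poisson(mu)
    data = pd.DataFrame({"x": x, "y": y})
    spec = M.ModelSpec(response="y", smooths=(M.SmoothTerm("x", k=12),),
                       group=None, ar1=False, family="poisson")
    fit = M.fit_amm(data, spec)
    pred = fit.predict(pd.DataFrame({"x": x}), se=False)
    rmse = float(np.sqrt(np.mean((pred["fit"].to_numpy()
                                  - (2.0 + 0.8 * np.sin(x))) ** 2)))
    assert rmse < 0.15                      # on the log-link scale


def test_poisson_rejects_negative_response():
    data = pd.DataFrame({"x": np.arange(30.0), "y": np.arange(30.0) - 5})
    spec = M.ModelSpec(response="y", smooths=(M.SmoothTerm("x"),), group=None,
                       family="poisson")
    with pytest.raises(DataError, match="non-negative"):
        M.fit_amm(data, spec)


# ---------------------------------------------------------------------------
# Multinomial dive-type model
# ---------------------------------------------------------------------------


def _dive_type_data(rng, n=900):
    months = rng.choice([6, 7, 8, 9, 10], n)
    probs = {6: (0.8, 0.1, 0.1), 7: (0.7, 0.15, 0.15), 8: (0.6, 0.2, 0.2),
             9: (0.4, 0.3, 0.3), 10: (0.3, 0.3, 0.4)}
    classes = [rng.choice(["coastal", "benthic", "pelagic"], p=probs[m])
               for m in months]
    return pd.DataFrame({"month": months, "dive_class": classes,
                         "year": "2010", "age": "adult"})


def test_dive_type_model_selects_month_and_probs_sum_to_one(rng):
    data = _dive_type_data(rng)
    table, best, pframe = M.fit_dive_type_multinomial(
        data, candidates=((), ("month",)))
    assert table["model"].iloc[0] == "month"
    prob_cols = ["coastal", "benthic", "pelagic"]
    sums = pframe[prob_cols].sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-6)
    # month trend is reproduced in the fitted probabilities
    p = pframe.set_index("month")
    assert p.loc[6, "coastal"] > p.loc[10, "coastal"]


def test_dive_type_needs_two_categories():
    df = pd.DataFrame({"month": [6] * 30, "dive_class": ["coastal"] * 30})
    with pytest.raises(DataError, match=">= 2 observed categories"):
        M.fit_dive_type_multinomial(df, candidates=((),))


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def test_estimate_ar1(rng):
    n = 20000
    phi = 0.6
    x = np.empty(n)
    x[0] = rng.normal()
    for k in range(1, n):
        x[k] = phi * x[k - 1] + rng.normal(0, np.sqrt(1 - phi**2))
    assert M.estimate_ar1(x) == pytest.approx(phi, abs=0.02)
    assert M.estimate_ar1(np.zeros(10)) == 0.0
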