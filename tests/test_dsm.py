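"""Density surface model: penalized Tweedie GAM fitting and selection."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ltdsm.dsm import (
    DSMFit,
    SmootherSpec,
    SmoothTerm,
    _penalty_total,
    _pirls,
    dsm_from_json,
    dsm_to_json,
    fit_dsm,
    rank_dsm_models,
    select_best_dsm,
)


def _quiet_fit(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_dsm(*args, **kwargs)


@pytest.fixture(scope="module")
def offset_counts():
    rng = np.random.default_rng(21)
    n = 200
    A = rng.uniform(0.5, 3.0, n)
    x = rng.uniform(0, 10, n)
    mu = A * np.exp(-2.0 + 0.25 * x)
    y = rng.poisson(mu).astype(float)
    return pd.DataFrame({"n_groups": y, "effective_area": A, "x": x})


def test_intercept_only_matches_independent_glm(offset_counts):
    """The unpenalized intercept-plus-offset model must agree with an
    independently implemented Tweedie GLM to machine precision."""
    y = offset_counts["n_groups"].to_numpy()
    A = offset_counts["effective_area"].to_numpy()
    fit = _quiet_fit(offset_counts, SmootherSpec(()), power=1.5)
    glm = sm.GLM(
        y,
        np.ones((len(y), 1)),
        family=sm.families.Tweedie(var_power=1.5, link=sm.families.links.Log()),
        offset=np.log(A),
    ).fit()
    assert fit.coef[0] == pytest.approx(glm.params[0], abs=1e-8)


def test_intercept_only_poisson_limit_is_offset_weighted_mean(offset_counts):
    """As p -> 1 the intercept-only fit reduces to rate = sum y / sum A."""
    y = offset_counts["n_groups"].to_numpy()
    A = offset_counts["effective_area"].to_numpy()
    fit = _quiet_fit(offset_counts, SmootherSpec(()), power=1.0001)
    assert np.exp(fit.coef[0]) == pytest.approx(y.sum() / A.sum(), rel=1e-4)


def test_unpenalized_linear_term_matches_statsmodels(offset_counts):
    y = offset_counts["n_groups"].to_numpy()
    A = offset_counts["effective_area"].to_numpy()
    X = np.column_stack([np.ones(len(y)), offset_counts["x"]])
    coef, _, _, edf, _ = _pirls(X, y, np.log(A), np.zeros((2, 2)), 1.5)
    glm = sm.GLM(
        y, X,
        family=sm.families.Tweedie(var_power=1.5, link=sm.families.links.Log()),
        offset=np.log(A),
    ).fit()
    assert np.allclose(coef, glm.params, atol=1e-5)
    assert edf == pytest.approx(2.0, abs=1e-8)


def test_fit_agrees_with_mgcv_oracle(tmp_path):
    """Same data, same model family: the fitted surface must agree with
    mgcv's thin-plate Tweedie GAM (independent implementation)."""
    rng = np.random.default_rng(31)
    n = 250
    x = rng.uniform(0, 10, n)
    A = rng.uniform(0.5, 3.0, n)
    mu = A * np.exp(-1.5 + 0.8 * np.sin(x))
    p, phi = 1.5, 0.9
    lam = mu ** (2 - p) / (phi * (2 - p))
    alpha = (2 - p) / (p - 1)
    Npois = rng.poisson(lam)
    y = np.where(Npois > 0, rng.gamma(np.maximum(Npois, 1) * alpha, phi * (p - 1) * mu ** (p - 1)), 0.0)
    df = pd.DataFrame({"n_groups": y, "effective_area": A, "x": x})
    fit = _quiet_fit(df, SmootherSpec((SmoothTerm(("x",), k=10),)))

    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rscript = f"""
    library(mgcv)
    d <- read.csv("{csv}")
    m <- gam(n_groups ~ s(x, bs="tp", k=10) + offset(log(effective_area)),
             family=tw(), data=d, method="GCV.Cp")
    cat(m$family$getTheta(TRUE), "\n")
    write.table(fitted(m), "{tmp_path}/f.txt", row.names=FALSE, col.names=FALSE)
    """
    subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
    mgcv_fitted = np.loadtxt(tmp_path / "f.txt")
    mgcv_power = float(
        subprocess.run(
            ["Rscript", "-e", rscript], check=True, capture_output=True, text=True
        ).stdout.split()[-1]
    )
    corr = np.corrcoef(fit.fitted, mgcv_fitted)[0, 1]
    rel_rmse = np.sqrt(np.mean((fit.fitted - mgcv_fitted) ** 2)) / np.mean(mgcv_fitted)
    assert corr > 0.99
    assert rel_rmse < 0.10
    assert abs(fit.power - mgcv_power) < 0.1


def test_recovers_known_spatial_surface():
    """600 segments over a log-linear intensity in (x, y): the fitted
    surface must correlate strongly with the truth."""
    rng = np.random.default_rng(41)
    n = 600
    xy = rng.uniform(0, 100, (n, 2))
    A = rng.uniform(1.0, 3.0, n)
    eta_true = -3.0 + 0.02 * xy[:, 0] + 0.015 * xy[:, 1]
    mu = A * np.exp(eta_true)
    y = rng.poisson(mu).astype(float)
    df = pd.DataFrame(
        {"n_groups": y, "effective_area": A, "mid_x": xy[:, 0], "mid_y": xy[:, 1]}
    )
    fit = _quiet_fit(df, SmootherSpec((SmoothTerm(("mid_x", "mid_y"), k=20),)))
    assert np.corrcoef(np.log(fit.fitted / A), eta_true)[0, 1] > 0.8


def test_noise_covariate_rarely_improves_gcv():
    """Adding a pure-noise smooth should not typically lower GCV (its
    unpenalized linear part can win by chance in a minority of cases)."""
    rng = np.random.default_rng(5)
    wins = 0
    N = 50
    for _rep in range(N):
        n = 120
        x = rng.uniform(0, 10, n)
        A = rng.uniform(0.5, 3.0, n)
        mu = A * np.exp(-1.2 + 0.3 * np.sin(x))
        y = rng.poisson(mu).astype(float)
        df = pd.DataFrame(
            {"n_groups": y, "effective_area": A, "x": x, "noise": rng.normal(size=n)}
        )
        f0 = _quiet_fit(df, SmootherSpec((SmoothTerm(("x",), k=8),)), power=1.2)
        f1 = _quiet_fit(
            df, SmootherSpec((SmoothTerm(("x",), k=8), SmoothTerm(("noise",), k=8))),
            power=1.2,
        )
        wins += f1.gcv >= f0.gcv - 1e-9
    assert wins / N >= 0.6


def test_infinite_smoothing_collapses_to_plane():
    """At lambda -> inf the 2-D smooth keeps only its polynomial null
    space: the link-scale surface becomes a plane in (x, y)."""
    rng = np.random.default_rng(51)
    n = 300
    xy = rng.uniform(0, 50, (n, 2))
    A = np.ones(n)
    mu = A * np.exp(-2.0 + 0.05 * np.sin(xy[:, 0]) * np.cos(xy[:, 1]))
    y = rng.poisson(mu).astype(float)
    df = pd.DataFrame(
        {"n_groups": y, "effective_area": A, "mid_x": xy[:, 0], "mid_y": xy[:, 1]}
    )
    from ltdsm.dsm import _assemble

    X, penalties, _ = _assemble(df, SmootherSpec((SmoothTerm(("mid_x", "mid_y"), k=15),)))
    S = _penalty_total(penalties, np.array([1e12]), X.shape[1])
    coef, _, _, edf, _ = _pirls(X, y, np.log(A), S, 1.5)
    eta = X @ coef
    # a plane in (x, y) explains the collapsed surface essentially exactly
    Q = np.column_stack([np.ones(n), xy])
    resid = eta - Q @ np.linalg.lstsq(Q, eta, rcond=None)[0]
    assert np.max(np.abs(resid)) < 1e-6
    assert edf == pytest.approx(3.0, abs=0.01)  # intercept + plane


def test_invariants_of_fit(offset_counts):
    fit = _quiet_fit(offset_counts, SmootherSpec((SmoothTerm(("x",), k=8),)))
    assert 1.0 < fit.power < 2.0
    assert 0.0 <= fit.deviance_explained <= 100.0
    evals = np.linalg.eigvalsh(fit.cov)
    assert evals.min() >= -1e-8 * max(evals.max(), 1.0)


def test_rank_table_deltas_and_tiebreak():
    def fake(label, n_terms, aic, gcv):
        terms = tuple(SmoothTerm((f"v{i}",), 5) for i in range(n_terms))
        f = DSMFit(spec=SmootherSpec(terms, label=label))
        f.aic, f.gcv, f.r2, f.deviance, f.null_deviance, f.n = aic, gcv, 0.1, 60.0, 100.0, 500
        return f

    g8 = fake("g8", 2, 890.25, 265.03)
    g2 = fake("g2", 2, 891.11, 265.06)
    g1 = fake("g1", 1, 893.95, 268.99)
    table = rank_dsm_models([g1, g2, g8])
    assert table["model"].tolist() == ["g8", "g2", "g1"]
    assert table["delta_aic"].tolist() == pytest.approx([0.0, 0.86, 3.70])
    assert table["delta_gcv"].iloc[1] == pytest.approx(0.03)
    # permutation invariance
    pd.testing.assert_frame_equal(table, rank_dsm_models([g8, g1, g2]))
    # tie-break: within 2 AIC of the best, fewer covariates wins
    g_simple = fake("g0", 0, 891.5, 266.0)
    assert select_best_dsm([g8, g2, g1, g_simple]).spec.label == "g0"
    # far-apart models: plain AIC winner
    assert select_best_dsm([g8, g1]).spec.label == "g8"


def test_rank_requires_shared_data():
    a = DSMFit(spec=SmootherSpec((), label="a"))
    b = DSMFit(spec=SmootherSpec((), label="b"))
    a.n, b.n = 100, 90
    a.aic = b.aic = 1.0
    a.gcv = b.gcv = 1.0
    a.deviance = b.deviance = 1.0
    a.null_deviance = b.null_deviance = 2.0
    with pytest.raises(ValueError):
        rank_dsm_models([a, b])


def test_serialization_roundtrip(offset_counts):
    fit = _quiet_fit(offset_counts, SmootherSpec((SmoothTerm(("x",), k=8),), label="g"))
    back = dsm_from_json(dsm_to_json(fit))
    new = pd.DataFrame({"x": np.linspace(0.5, 9.5, 40)})
    eta1, se1 = fit.predict_link(new)
    eta2, se2 = back.predict_link(new)
    assert np.allclose(eta1, eta2, atol=1e-12)
    assert np.allclose(se1, se2, atol=1e-12)
    assert back.power == fit.power


def test_missing_covariates_dropped_with_warning(offset_counts):
    df = offset_counts.copy()
    df.loc[df.index[:5], "x"] = np.nan
    with pytest.warns(UserWarning, match="missing covariates"):
        fit = fit_dsm(df, SmootherSpec((SmoothTerm(("x",), k=8),)), power=1.3)
    assert fit.n == len(df) - 5


def test_nonpositive_area_rejected(offset_counts):
    df = offset_counts.copy()
    df.loc[df.index[0], "effective_area"] = 0.0
    with pytest.raises(ValueError):
        fit_dsm(df, SmootherSpec(()), power=1.5)
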