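"""Detection functions: evaluation, fitting, esw, GoF, ranking, group size."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from ltdsm.detection import (
    DetectionConfig,
    DetectionFit,
    average_detectability,
    cvm_goodness_of_fit,
    effective_strip_width,
    evaluate_detection,
    expected_group_size,
    fit_detection,
    fitted_cdf,
    halfnormal_esw,
    rank_detection_models,
)

W = 1750.0


def _manual_fit(sigma, config, n_used=10):
    """A DetectionFit at known parameters (no data fitting)."""
    fit = DetectionFit(
        config=config,
        beta=np.array([np.log(sigma)]),
        shape_b=None if config.key == "half-normal" else 2.0,
        adj_coeffs=np.empty(0),
        loglik=0.0,
        aic=0.0,
        n_used=n_used,
    )
    fit._data_distances = np.linspace(10.0, config.truncation_w * 0.9, n_used)
    fit._data_covariates = {}
    return fit


@pytest.mark.parametrize(
    "key,sigma,b,x,expected",
    [
        ("half-normal", 600.0, None, 0.0, 1.0),
        ("half-normal", 600.0, None, 600.0, np.exp(-0.5)),
        ("hazard-rate", 500.0, 2.0, 500.0, 1.0 - np.exp(-1.0)),
        ("hazard-rate", 500.0, 2.0, 0.0, 1.0),
    ],
)
def test_evaluate_analytic_values(key, sigma, b, x, expected):
    cfg = DetectionConfig(key, "none", (), W)
    params = {"beta": [np.log(sigma)], "shape_b": b, "adj_coeffs": []}
    assert evaluate_detection(x, None, params, cfg) == pytest.approx(expected, rel=1e-12)


def test_negative_distance_rejected():
    cfg = DetectionConfig("half-normal", "none", (), W)
    params = {"beta": [np.log(600.0)], "shape_b": None, "adj_coeffs": []}
    with pytest.raises(ValueError):
        evaluate_detection(-5.0, None, params, cfg)


def test_cosine_adjustment_rescales_to_one_at_zero():
    cfg = DetectionConfig("half-normal", "cosine", (), W)
    params = {"beta": [np.log(600.0)], "shape_b": None, "adj_coeffs": [0.3]}
    assert evaluate_detection(0.0, None, params, cfg) == pytest.approx(1.0, abs=1e-14)
    grid = np.linspace(0, W, 300)
    g = evaluate_detection(grid, None, params, cfg)
    assert np.all(g >= 0) and np.all(g <= 1.0 + 1e-12)


def test_invalid_config_combinations():
    with pytest.raises(ValueError):
        DetectionConfig("hazard-rate", "cosine", (), W)
    with pytest.raises(ValueError):
        DetectionConfig("half-normal", "none", (), -1.0)


def test_fit_recovers_generating_scale(halfnormal_fit):
    sigma_hat = float(np.exp(halfnormal_fit.beta[0]))
    assert abs(sigma_hat - 600.0) / 600.0 < 0.05


def test_fit_rejects_degenerate_sample():
    one = pd.DataFrame({"perp_distance": [100.0, 2000.0]})  # one survives truncation
    with pytest.raises(ValueError):
        fit_detection(one, DetectionConfig("half-normal", "none", (), W))


def test_esw_closed_form_across_scales():
    """Quadrature esw equals sigma sqrt(pi/2) erf(w / (sigma sqrt2)) to 1e-6."""
    for sigma in [100.0, 300.0, 600.0, 1200.0, 5000.0]:
        cfg = DetectionConfig("half-normal", "none", (), W)
        fit = _manual_fit(sigma, cfg)
        esw, _ = effective_strip_width(fit)
        assert esw == pytest.approx(halfnormal_esw(sigma, W), rel=1e-6)


def test_esw_flat_limit_equals_w():
    fit = _manual_fit(1e9, DetectionConfig("half-normal", "none", (), W))
    esw, _ = effective_strip_width(fit)
    assert esw == pytest.approx(W, rel=1e-9)


def test_esw_pbar_identity(halfnormal_fit):
    assert halfnormal_fit.esw == pytest.approx(
        halfnormal_fit.p_bar * W, rel=1e-9
    )
    assert average_detectability(halfnormal_fit) == pytest.approx(
        halfnormal_fit.esw / W, rel=1e-12
    )


def test_covariate_fit_identity_and_se(halfnormal_sample):
    rng = np.random.default_rng(5)
    df = halfnormal_sample.copy()
    df["seastate"] = rng.integers(0, 5, len(df)).astype(float)
    fit = fit_detection(df, DetectionConfig("half-normal", "none", ("seastate",), W))
    assert fit.esw == pytest.approx(fit.p_bar * W, rel=1e-9)
    assert fit.esw_se > 0


def test_cvm_minimum_statistic():
    """Distances placed so the fitted CDF hits (2i-1)/(2n) give the
    smallest possible statistic W^2 = 1/(12 n)."""
    n = 5
    cfg = DetectionConfig("half-normal", "none", (), W)
    fit = _manual_fit(600.0, cfg, n_used=n)
    targets = (2 * np.arange(1, n + 1) - 1) / (2.0 * n)
    xs = [brentq(lambda x, t=t: float(fitted_cdf(fit, [x])[0]) - t, 1e-6, W) for t in targets]
    fit._data_distances = np.array(xs)
    stat, p = cvm_goodness_of_fit(fit)
    assert stat == pytest.approx(1.0 / (12 * n), rel=1e-6)
    assert 0 < p <= 1


def test_cvm_rejects_wrong_model():
    rng = np.random.default_rng(6)
    x = rng.uniform(0, W, 300)  # uniform distances: nothing like half-normal sigma=300
    fit = _manual_fit(300.0, DetectionConfig("half-normal", "none", (), W), n_used=300)
    fit._data_distances = x
    _, p = cvm_goodness_of_fit(fit)
    assert p < 0.01


def test_rank_table_delta_aic_and_permutation(halfnormal_sample):
    fits = [
        fit_detection(halfnormal_sample, DetectionConfig("half-normal", "none", (), W, label="m1")),
        fit_detection(halfnormal_sample, DetectionConfig("half-normal", "cosine", (), W, label="c1")),
        fit_detection(halfnormal_sample, DetectionConfig("hazard-rate", "none", (), W, label="h1")),
    ]
    t1 = rank_detection_models(fits)
    t2 = rank_detection_models(fits[::-1])
    pd.testing.assert_frame_equal(t1, t2)
    assert t1["delta_aic"].iloc[0] == 0.0
    assert (t1["delta_aic"].to_numpy() == np.sort(t1["delta_aic"].to_numpy())).all()
    assert t1["aic"].to_numpy()[1:] - t1["aic"].to_numpy()[0] == pytest.approx(
        t1["delta_aic"].to_numpy()[1:]
    )
    # hazard-rate rows carry the near-zero diagnostic, others do not
    hr = t1[t1["key"] == "hazard-rate"]
    assert np.isfinite(hr["near_zero_ratio"]).all()


def test_rank_requires_identical_data(halfnormal_sample):
    f1 = fit_detection(halfnormal_sample, DetectionConfig("half-normal", "none", (), W))
    f2 = fit_detection(halfnormal_sample.iloc[:-10], DetectionConfig("half-normal", "none", (), W))
    with pytest.raises(ValueError):
        rank_detection_models([f1, f2])


def test_group_size_arithmetic_branch():
    """Sizes {1,1,2} with no size-distance relationship: plain mean 4/3."""
    df = pd.DataFrame(
        {"perp_distance": [100.0, 900.0, 500.0], "group_size": [1, 1, 2]}
    )
    fit = _manual_fit(600.0, DetectionConfig("half-normal", "none", (), W), n_used=3)
    est = expected_group_size(df, fit, alpha=0.05)
    assert est.method == "arithmetic-mean"
    assert est.expected_size == pytest.approx(4.0 / 3.0)


def test_group_size_regression_corrects_size_bias():
    """When larger groups are seen farther out, the regression estimate
    must fall below the naive mean of detected sizes and approach the
    generating mean."""
    rng = np.random.default_rng(7)
    sigma0, true_mean = 400.0, 1.5
    sizes = 1 + rng.poisson(true_mean - 1.0, 20000)
    x = rng.uniform(0.0, W, sizes.size)  # uniform exposure across the strip
    sigma = sigma0 * np.power(sizes, 0.9)  # strong size effect on detectability
    detected = rng.uniform(size=sizes.size) < np.exp(-(x**2) / (2.0 * sigma**2))
    df = pd.DataFrame({"perp_distance": x[detected], "group_size": sizes[detected]})
    fit = fit_detection(df, DetectionConfig("half-normal", "none", (), W))
    est = expected_group_size(df, fit, alpha=0.15)
    naive = df["group_size"].mean()
    assert est.method == "size-bias-regression"
    assert est.expected_size < naive
    assert abs(est.expected_size - true_mean) < abs(naive - true_mean)


def test_noise_covariate_cannot_beat_nested_model_badly(halfnormal_sample):
    """A pure-noise covariate costs about one AIC unit on average; it can
    never improve the fit by more than chance allows."""
    rng = np.random.default_rng(8)
    deltas = []
    for rep in range(20):
        sub = halfnormal_sample.sample(150, random_state=rep).copy()
        sub["noise"] = rng.normal(size=len(sub))
        f0 = fit_detection(sub, DetectionConfig("half-normal", "none", (), W))
        f1 = fit_detection(sub, DetectionConfig("half-normal", "none", ("noise",), W))
        deltas.append(f1.aic - f0.aic)
    assert np.mean(deltas) <= 2.0 + 0.1
    assert np.mean(deltas) >= -0.5
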