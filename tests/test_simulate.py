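"""Synthetic survey generator: known-truth properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ltdsm.simulate import (
    DetectionSim,
    SimulationConfig,
    SurfaceSpec,
    expected_encounters,
    simulate,
    simulate_population,
    simulate_survey,
    zt_poisson_mean,
)

CONSTANT = SurfaceSpec(log_density0=np.log(0.01), coefficients={})


def test_population_mean_count_matches_surface_integral():
    """Constant D = 0.01 groups/km^2 over 10^4 km^2: mean count ~ 100."""
    cfg = SimulationConfig(extent_km=(100.0, 100.0), surface=CONSTANT)
    counts = [
        len(simulate_population(cfg, np.random.default_rng(s))) for s in range(200)
    ]
    m = np.mean(counts)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(m - 100.0) < 3 * se + 1e-9


def test_nonfinite_intensity_is_config_error():
    cfg = SimulationConfig(
        surface=SurfaceSpec(log_density0=np.nan, coefficients={}), seed=1
    )
    with pytest.raises(ValueError):
        simulate_population(cfg)


def test_tiny_intensity_gives_empty_population():
    cfg = SimulationConfig(
        surface=SurfaceSpec(log_density0=np.log(1e-12), coefficients={}), seed=1
    )
    assert len(simulate_population(cfg)) == 0


def test_zero_truncated_poisson_mean():
    cfg = SimulationConfig(size_law="zt-poisson", size_param=0.3)
    rng = np.random.default_rng(9)
    from ltdsm.simulate import _draw_sizes

    draws = _draw_sizes(100_000, cfg, rng)
    assert draws.min() >= 1
    expected = zt_poisson_mean(0.3)  # ~ 1.157
    assert expected == pytest.approx(0.3 / (1 - np.exp(-0.3)))
    assert abs(draws.mean() - expected) < 3 * draws.std() / np.sqrt(draws.size)


def test_same_seed_identical_output():
    cfg = SimulationConfig(seed=17)
    a, b = simulate(cfg), simulate(cfg)
    pd.testing.assert_frame_equal(a.groups, b.groups)
    pd.testing.assert_frame_equal(a.effort, b.effort)
    pd.testing.assert_frame_equal(a.sightings, b.sightings)
    assert a.truth == b.truth


def test_perfect_detection_sees_every_strip_group():
    """sigma -> inf: every group in the one-sided strip is detected and
    nothing beyond the truncation distance is recorded."""
    cfg = SimulationConfig(
        surface=SurfaceSpec(log_density0=np.log(0.05), coefficients={}),
        detection=DetectionSim(sigma_m=1e9),
        n_transects=5,
        seed=23,
    )
    sv = simulate(cfg)
    assert (sv.sightings["perp_distance"] <= cfg.detection.truncation_w_m).all()
    # with g = 1 the encounter count must match the analytic strip expectation
    w_km = cfg.detection.truncation_w_m / 1000.0
    expected = expected_encounters(cfg, w_km, sv.truth["total_effort_km"])
    assert abs(len(sv.sightings) - expected) < 4 * np.sqrt(expected)


def test_expected_encounters_arithmetic():
    cfg = SimulationConfig(
        surface=SurfaceSpec(log_density0=np.log(0.02), coefficients={}),
        n_transects=20, transect_length_km=50.0,
    )
    assert expected_encounters(cfg, 0.5, 1000.0) == pytest.approx(10.0)
    zero = SimulationConfig(
        surface=SurfaceSpec(log_density0=-50.0, coefficients={})
    )
    assert expected_encounters(zero, 0.5, 1000.0) == pytest.approx(0.0, abs=1e-12)


def test_expected_encounters_requires_constant_surface():
    with pytest.raises(ValueError):
        expected_encounters(SimulationConfig(), 0.5)


def test_encounter_rate_matches_simulation():
    """Mean detections over seeds agree with D x esw x L (half-normal
    esw from the closed form)."""
    from ltdsm.detection import halfnormal_esw

    det = DetectionSim(sigma_m=600.0)
    cfg = SimulationConfig(
        extent_km=(120.0, 120.0),
        surface=SurfaceSpec(log_density0=np.log(0.03), coefficients={}),
        detection=det, n_transects=10, seed=0,
    )
    esw_km = halfnormal_esw(600.0, det.truncation_w_m) / 1000.0
    counts, expect = [], []
    for s in range(120):
        sv = simulate(SimulationConfig(**{**cfg.__dict__, "seed": s}))
        counts.append(len(sv.sightings))
        expect.append(expected_encounters(cfg, esw_km, sv.truth["total_effort_km"]))
    mean_n, mean_e = np.mean(counts), np.mean(expect)
    se = np.std(counts, ddof=1) / np.sqrt(len(counts))
    assert abs(mean_n - mean_e) < 3 * se


def test_detection_thinning_matches_g_by_distance():
    """Binned detection frequency reproduces g(x) (chi-square, a = 0.01)."""
    rng = np.random.default_rng(77)
    W, sigma = 1750.0, 600.0
    n = 100_000
    x = rng.uniform(0, W, n)
    detected = rng.uniform(size=n) < np.exp(-(x**2) / (2 * sigma**2))
    edges = np.linspace(0, W, 11)
    chi2 = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (x >= lo) & (x < hi)
        p = np.exp(-(((lo + hi) / 2) ** 2) / (2 * sigma**2))
        obs = detected[m].sum()
        exp = m.sum() * p
        var = m.sum() * p * (1 - p)
        chi2 += (obs - exp) ** 2 / var
    assert chi2 < stats.chi2.ppf(0.99, df=10)


def test_horvitz_thompson_with_true_detection_recovers_strip_count():
    """HT with the TRUE g (no fitting anywhere) is unbiased for the
    number of groups inside the covered strips."""
    det = DetectionSim(sigma_m=600.0)
    w_km = det.truncation_w_m / 1000.0
    errs = []
    for s in range(60):
        cfg = SimulationConfig(
            extent_km=(120.0, 120.0),
            surface=SurfaceSpec(log_density0=np.log(0.05), coefficients={}),
            detection=det, n_transects=12, seed=s,
        )
        sv = simulate(cfg)
        if len(sv.sightings) == 0:
            continue
        g = np.exp(-(sv.sightings["perp_distance"] ** 2) / (2 * det.sigma_m**2))
        ht = (1.0 / g).sum()
        # geometric truth: distinct groups inside the union of covered strips
        gxy = sv.groups[["x", "y"]].to_numpy()
        in_strip = np.zeros(len(gxy), dtype=bool)
        for _, tr in sv.effort.groupby("transect_id"):
            p0 = tr[["x", "y"]].iloc[0].to_numpy()
            p1 = tr[["x", "y"]].iloc[-1].to_numpy()
            u = (p1 - p0) / np.linalg.norm(p1 - p0)
            rel = gxy - p0
            along = rel @ u
            cross = u[0] * rel[:, 1] - u[1] * rel[:, 0]
            in_strip |= (
                (along >= 0)
                & (along <= np.linalg.norm(p1 - p0))
                & (cross > 0)
                & (cross <= w_km)
            )
        errs.append((ht - in_strip.sum()) / in_strip.sum())
    se = np.std(errs, ddof=1) / np.sqrt(len(errs))
    assert abs(np.mean(errs)) < 3 * se + 0.01


def test_cluster_process_adds_aggregations():
    base = SimulationConfig(seed=5)
    clustered = SimulationConfig(seed=5, cluster_parent_rate=0.001,
                                 cluster_mean_size=25.0)
    g0 = simulate_population(base)
    g1 = simulate_population(clustered)
    assert len(g1) > len(g0)


def test_geometric_size_law():
    cfg = SimulationConfig(size_law="geometric", size_param=0.5)
    from ltdsm.simulate import _draw_sizes

    draws = _draw_sizes(50_000, cfg, np.random.default_rng(8))
    assert draws.min() >= 1
    assert abs(draws.mean() - 2.0) < 0.05


def test_sightings_are_subset_of_population():
    sv = simulate(SimulationConfig(seed=29))
    pop = set(zip(np.round(sv.groups["x"], 9), np.round(sv.groups["y"], 9)))
    for x, y in zip(sv.sightings["x"], sv.sightings["y"]):
        assert (round(x, 9), round(y, 9)) in pop
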