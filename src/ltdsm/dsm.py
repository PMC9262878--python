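"""Density surface model: penalized Tweedie additive model of counts.

Models the number of groups per effort segment as

    n_groups_i ~ Tweedie(mu_i, p, phi),  1 < p < 2
    log mu_i = log A_i + intercept + sum_j f_j(covariates_i)

where A_i is the effectively covered area of segment i (the offset) and
each f_j is a thin-plate regression spline (1-D, or the 2-D spatial
smooth over segment midpoint x, y).  Fitting is penalized IRLS; one
smoothing parameter per term is chosen by minimising the GCV score
n D / (n - edf)^2 on the deviance scale, the Tweedie power p by a 1-D
profile over a grid maximising the compound Poisson-gamma series
log-likelihood, and the dispersion phi by the Pearson estimator.

Prediction onto new covariates returns the linear predictor and its
delta-method standard error from the coefficient covariance
(X' W X + S)^{-1} phi.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import ThinPlateSmooth
from .tweedie import tweedie_deviance, tweedie_loglik

__all__ = [
    "SmoothTerm",
    "SmootherSpec",
    "DSMFit",
    "fit_dsm",
    "rank_dsm_models",
    "select_best_dsm",
    "dsm_to_json",
    "dsm_from_json",
]

P_GRID = np.round(np.arange(1.05, 1.96, 0.05), 2)
_LOG_LAMBDA_RANGE = (-5.0, 7.0)


@dataclass(frozen=True)
class SmoothTerm:
    """One thin-plate smooth over 1 or 2 covariate columns."""

    variables: tuple
    k: int = 10

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        if len(self.variables) not in (1, 2):
            raise ValueError("a smooth takes 1 or 2 variables")
        if self.k < 3:
            raise ValueError("basis dimension k must be >= 3")

    @property
    def label(self) -> str:
        return "s(" + ", ".join(self.variables) + ")"


@dataclass(frozen=True)
class SmootherSpec:
    """Model formula: smooth terms + Tweedie family + offset column."""

    terms: tuple = ()
    offset_name: str = "effective_area"
    response: str = "n_groups"
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        spatial = [t for t in self.terms if len(t.variables) == 2]
        if len(spatial) > 1:
            raise ValueError("at most one 2-D (spatial) smooth is allowed")

    @property
    def formula(self) -> str:
        return " + ".join(t.label for t in self.terms) or "1"


@dataclass
class DSMFit:
    spec: SmootherSpec
    smooths: list = field(repr=False, default_factory=list)
    coef: np.ndarray = None
    cov: np.ndarray = field(default=None, repr=False)
    lambdas: np.ndarray = None
    power: float = np.nan
    phi: float = np.nan
    edf: float = np.nan
    loglik: float = np.nan
    aic: float = np.nan
    gcv: float = np.nan
    deviance: float = np.nan
    null_deviance: float = np.nan
    r2: float = np.nan
    n: int = 0
    fitted: np.ndarray = field(default=None, repr=False)

    @property
    def deviance_explained(self) -> float:
        """Percent deviance explained, 100 (1 - D / D_null)."""
        return 100.0 * (1.0 - self.deviance / self.null_deviance)

    def design(self, data: pd.DataFrame) -> np.ndarray:
        """Model matrix (intercept + smooth blocks) for new data."""
        n = len(data)
        blocks = [np.ones((n, 1))]
        for term, smooth in zip(self.spec.terms, self.smooths):
            x = data[list(term.variables)].to_numpy(dtype=float)
            blocks.append(smooth.basis(x))
        return np.hstack(blocks)

    def predict_link(self, data: pd.DataFrame):
        """(eta, se_eta) on the link scale, excluding any offset."""
        X = self.design(data)
        eta = X @ self.coef
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov, X), 0.0))
        return eta, se


# ---------------------------------------------------------------------------
# fitting internals


def _assemble(data: pd.DataFrame, spec: SmootherSpec):
    """Build design matrix, per-term penalty blocks and smooth objects."""
    n = len(data)
    blocks = [np.ones((n, 1))]
    penalties = []  # (start, S) in full-design coordinates
    smooths = []
    pos = 1
    for term in spec.terms:
        x = data[list(term.variables)].to_numpy(dtype=float)
        sm = ThinPlateSmooth(x, k=term.k)
        smooths.append(sm)
        blocks.append(sm.design)
        penalties.append((pos, sm.penalty))
        pos += sm.n_coef
    X = np.hstack(blocks)
    return X, penalties, smooths


def _penalty_total(penalties, lambdas, p_dim):
    S = np.zeros((p_dim, p_dim))
    for lam, (start, Sj) in zip(lambdas, penalties):
        k = Sj.shape[0]
        S[start : start + k, start : start + k] += lam * Sj
    return S


def _pirls(X, y, offset, S, power, max_iter=100, tol=1e-8):
    """Penalized IRLS for the Tweedie log-link model.

    Returns (coef, mu, deviance, edf, XWX) at convergence.
    """
    n, p_dim = X.shape
    mu = np.maximum(y, 0.0) + np.mean(y) * 0.5 + 0.1
    eta = np.log(mu) - offset
    coef = None
    dev_prev = np.inf
    for _ in range(max_iter):
        w = np.power(mu, 2.0 - power)
        z = eta + (y - mu) / mu
        XW = X * w[:, None]
        A = XW.T @ X + S
        b = XW.T @ z
        try:
            new_coef = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            warnings.warn("rank-deficient penalized system; using pseudo-inverse")
            new_coef = np.linalg.lstsq(A, b, rcond=None)[0]
        # step-halving safeguard against divergence of the log link
        step = 1.0
        for _half in range(30):
            trial = new_coef if coef is None else coef + step * (new_coef - coef)
            eta_t = X @ trial
            mu_t = np.exp(np.clip(eta_t + offset, -30.0, 30.0))
            dev = float(np.sum(tweedie_deviance(y, mu_t, power)))
            if np.isfinite(dev) and dev <= dev_prev + 1e-4 * max(abs(dev_prev), 1.0):
                break
            step *= 0.5
        else:
            raise RuntimeError("IRLS step-halving failed to find a finite deviance")
        coef, eta, mu = trial, eta_t, mu_t
        if abs(dev_prev - dev) < tol * (abs(dev) + 0.1):
            dev_prev = dev
            break
        dev_prev = dev
    w = np.power(mu, 2.0 - power)
    XW = X * w[:, None]
    XWX = XW.T @ X
    A = XWX + S
    edf = float(np.trace(np.linalg.solve(A, XWX)))
    return coef, mu, dev_prev, edf, XWX


def _gcv_score(X, y, offset, penalties, log10_lams, power):
    n = len(y)
    S = _penalty_total(penalties, 10.0 ** np.asarray(log10_lams), X.shape[1])
    try:
        _, _, dev, edf, _ = _pirls(X, y, offset, S, power)
    except RuntimeError:
        return np.inf
    denom = max(n - edf, 1e-3)
    return n * dev / denom**2


def _golden_section(fun, lo, hi, tol=1e-2, max_iter=40):
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return (a + b) / 2.0


def _select_lambdas(X, y, offset, penalties, power, start=None, cycles=2):
    """Coordinate-wise golden-section GCV minimisation, deterministic."""
    m = len(penalties)
    log_lams = np.zeros(m) if start is None else np.array(start, dtype=float)
    for _cycle in range(cycles):
        for j in range(m):
            def score(v, j=j):
                trial = log_lams.copy()
                trial[j] = v
                return _gcv_score(X, y, offset, penalties, trial, power)

            log_lams[j] = _golden_section(score, *_LOG_LAMBDA_RANGE, tol=5e-2)
    return log_lams


def fit_dsm(
    data: pd.DataFrame,
    spec: SmootherSpec,
    power: float | None = None,
    power_grid=P_GRID,
) -> DSMFit:
    """Fit the density surface model to a segment table.

    ``data`` must carry the response column (group counts), the offset
    column (effective area, km^2, > 0) and every covariate named in the
    smooth terms; rows with missing covariates are dropped with a
    warning.  Pass ``power`` to fix the Tweedie power instead of
    profiling it over ``power_grid``.
    """
    needed = [spec.response, spec.offset_name] + sorted(
        {v for t in spec.terms for v in t.variables}
    )
    d = data[needed + [c for c in data.columns if c not in needed]].copy()
    ok = np.isfinite(d[needed].to_numpy(dtype=float)).all(axis=1)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} segment(s) with missing covariates")
        d = d[ok]
    y = d[spec.response].to_numpy(dtype=float)
    A = d[spec.offset_name].to_numpy(dtype=float)
    if np.any(A <= 0):
        raise ValueError("effective areas must be positive")
    offset = np.log(A)
    n = len(y)

    X, penalties, smooths = _assemble(d, spec)

    # 1) smoothing parameters by GCV at a central power
    p0 = power if power is not None else 1.5
    log_lams = (
        _select_lambdas(X, y, offset, penalties, p0) if penalties else np.empty(0)
    )

    # 2) profile the Tweedie power on the series likelihood
    if power is None:
        best = (None, -np.inf, None)
        for p_try in power_grid:
            S = _penalty_total(penalties, 10.0**log_lams, X.shape[1])
            try:
                coef, mu, dev, edf, XWX = _pirls(X, y, offset, S, p_try)
            except RuntimeError:
                continue
            phi = float(np.sum((y - mu) ** 2 / mu**p_try) / max(n - edf, 1.0))
            ll = tweedie_loglik(y, mu, p_try, phi)
            if ll > best[1]:
                best = (float(p_try), ll, None)
        if best[0] is None:
            raise RuntimeError("Tweedie power profile failed at every grid point")
        power = best[0]
        # 3) re-select lambdas at the chosen power
        if penalties:
            log_lams = _select_lambdas(
                X, y, offset, penalties, power, start=log_lams, cycles=1
            )

    S = _penalty_total(penalties, 10.0**log_lams, X.shape[1])
    coef, mu, dev, edf, XWX = _pirls(X, y, offset, S, power)
    phi = float(np.sum((y - mu) ** 2 / mu**power) / max(n - edf, 1.0))
    ll = tweedie_loglik(y, mu, power, phi)
    aic = -2.0 * ll + 2.0 * (edf + 1.0)  # + 1 for the dispersion
    gcv = n * dev / max(n - edf, 1e-3) ** 2
    cov = np.linalg.inv(XWX + S) * phi  # Bayesian posterior covariance

    # null model (intercept + offset only) at the same power, for D_null
    X0 = np.ones((n, 1))
    _, _, dev0, _, _ = _pirls(X0, y, offset, np.zeros((1, 1)), power)

    resid_var = float(np.var(y - mu, ddof=0))
    r2 = 1.0 - (resid_var * (n - 1) / max(n - edf, 1.0)) / max(np.var(y, ddof=1), 1e-12)

    return DSMFit(
        spec=spec,
        smooths=smooths,
        coef=coef,
        cov=0.5 * (cov + cov.T),
        lambdas=10.0**log_lams,
        power=float(power),
        phi=phi,
        edf=edf,
        loglik=ll,
        aic=aic,
        gcv=gcv,
        deviance=dev,
        null_deviance=dev0,
        r2=r2,
        n=n,
        fitted=mu,
    )


# ---------------------------------------------------------------------------
# model comparison


def rank_dsm_models(fits: list[DSMFit]) -> pd.DataFrame:
    """Comparison table over candidate model formulas, ranked by AIC."""
    if not fits:
        raise ValueError("no fits to rank")
    n0 = fits[0].n
    if any(f.n != n0 for f in fits):
        raise ValueError("fits were not made on the same segment table")
    rows = [
        {
            "model": f.spec.label or f.spec.formula,
            "covariates": f.spec.formula,
            "n_terms": len(f.spec.terms),
            "aic": f.aic,
            "gcv": f.gcv,
            "r2": f.r2,
            "deviance_explained": f.deviance_explained,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values(["aic", "model"], kind="stable")
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["delta_gcv"] = table["gcv"] - table["gcv"].min()
    cols = [
        "model", "covariates", "aic", "gcv", "delta_aic", "delta_gcv",
        "r2", "deviance_explained", "n_terms",
    ]
    return table[cols].reset_index(drop=True)


def select_best_dsm(fits: list[DSMFit]) -> DSMFit:
    """Lowest AIC; within a 2-unit AIC tie the fewest-covariates model wins."""
    table = rank_dsm_models(fits)
    near = table[table["delta_aic"] < 2.0]
    chosen = near.sort_values(["n_terms", "aic"], kind="stable").iloc[0]["model"]
    for f in fits:
        if (f.spec.label or f.spec.formula) == chosen:
            return f
    raise RuntimeError("selection bookkeeping failed")  # pragma: no cover


# ---------------------------------------------------------------------------
# serialization (versioned JSON document)

_SCHEMA_VERSION = 1


def dsm_to_json(fit: DSMFit) -> str:
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "spec": {
            "label": fit.spec.label,
            "response": fit.spec.response,
            "offset_name": fit.spec.offset_name,
            "terms": [{"variables": list(t.variables), "k": t.k} for t in fit.spec.terms],
        },
        "coef": fit.coef.tolist(),
        "cov": fit.cov.tolist(),
        "lambdas": np.asarray(fit.lambdas).tolist(),
        "power": fit.power,
        "phi": fit.phi,
        "edf": fit.edf,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "gcv": fit.gcv,
        "deviance": fit.deviance,
        "null_deviance": fit.null_deviance,
        "r2": fit.r2,
        "n": fit.n,
        "smooths": [
            {
                "knots": sm._knots.tolist(),
                "shift": sm._shift.tolist(),
                "scale": sm._scale,
                "d": sm._d,
                "k": sm.k,
                "Uk": sm._Uk.tolist(),
                "Zc": sm._Zc.tolist(),
                "col_means": sm._col_means.tolist(),
            }
            for sm in fit.smooths
        ],
    }
    return json.dumps(doc)


def dsm_from_json(text: str) -> DSMFit:
    doc = json.loads(text)
    if doc["schema_version"] != _SCHEMA_VERSION:
        raise ValueError("unsupported fit-archive schema version")
    spec = SmootherSpec(
        terms=tuple(SmoothTerm(tuple(t["variables"]), t["k"]) for t in doc["spec"]["terms"]),
        offset_name=doc["spec"]["offset_name"],
        response=doc["spec"]["response"],
        label=doc["spec"]["label"],
    )
    smooths = []
    for s in doc["smooths"]:
        sm = ThinPlateSmooth.__new__(ThinPlateSmooth)
        sm.x = None
        sm.k = s["k"]
        sm._knots = np.array(s["knots"], dtype=float)
        sm._shift = np.array(s["shift"], dtype=float)
        sm._scale = float(s["scale"])
        sm._d = int(s["d"])
        sm._Uk = np.array(s["Uk"], dtype=float)
        sm._Zc = np.array(s["Zc"], dtype=float)
        sm._col_means = np.array(s["col_means"], dtype=float)
        smooths.append(sm)
    fit = DSMFit(
        spec=spec,
        smooths=smooths,
        coef=np.array(doc["coef"], dtype=float),
        cov=np.array(doc["cov"], dtype=float),
        lambdas=np.array(doc["lambdas"], dtype=float),
        power=doc["power"],
        phi=doc["phi"],
        edf=doc["edf"],
        loglik=doc["loglik"],
        aic=doc["aic"],
        gcv=doc["gcv"],
        deviance=doc["deviance"],
        null_deviance=doc["null_deviance"],
        r2=doc["r2"],
        n=doc["n"],
    )
    return fit
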