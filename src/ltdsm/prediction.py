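"""Grid prediction, CV masking and abundance summaries.

The fitted density surface is pushed onto a regular grid of cells (2.5
x 2.5 km by default, area 6.25 km^2).  Each cell gets a predicted
number of groups mu = exp(eta + log area), a delta-method standard
error and a coefficient of variation CV = 100 SE / mu.  Cells with
CV >= 100 are discarded before any totals are formed: outside the
data-supported region the model's extrapolation is not trusted.

Totals use the full coefficient covariance: SE(N)^2 = g' V g with
g = sum over retained cells of mu_c x_c, so between-cell correlation
induced by shared coefficients is kept.  Group abundance is converted
to individuals with the expected group size from the size-bias
regression; the default 95% CI is the normal interval N +/- 1.96 SE
from the model's standard error alone (detection-function and
group-size uncertainty are not propagated), with a log-normal interval
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import GroupSizeEstimate
from .dsm import DSMFit

__all__ = [
    "make_grid",
    "predict_cells",
    "mask_by_cv",
    "summarize_abundance",
    "AbundanceEstimate",
]

DEFAULT_CELL_KM = 2.5


@dataclass
class AbundanceEstimate:
    area_km2: float
    n_groups: float
    n_groups_se: float
    n_individuals: float
    density_groups: float
    density_individuals: float
    ci95_individuals: tuple
    ci95_groups: tuple
    group_size_used: float


def make_grid(x_min, x_max, y_min, y_max, cell_km: float = DEFAULT_CELL_KM) -> pd.DataFrame:
    """Cell-centre table covering [x_min, x_max] x [y_min, y_max]."""
    xs = np.arange(x_min + cell_km / 2.0, x_max, cell_km)
    ys = np.arange(y_min + cell_km / 2.0, y_max, cell_km)
    X, Y = np.meshgrid(xs, ys)
    return pd.DataFrame(
        {"x": X.ravel(), "y": Y.ravel(), "area_km2": cell_km * cell_km}
    )


def predict_cells(fit: DSMFit, grid: pd.DataFrame) -> pd.DataFrame:
    """Per-cell predicted groups, SE and CV (%).

    ``grid`` must carry the cells' covariates plus ``area_km2``.  Cells
    with any missing covariate are flagged no-data (NaN prediction) and
    excluded downstream.
    """
    needed = sorted({v for t in fit.spec.terms for v in t.variables})
    out = grid.copy()
    vals = out[needed].to_numpy(dtype=float) if needed else np.empty((len(out), 0))
    ok = np.isfinite(vals).all(axis=1)
    eta = np.full(len(out), np.nan)
    se_eta = np.full(len(out), np.nan)
    if ok.any():
        e, s = fit.predict_link(out[ok])
        eta[ok] = e
        se_eta[ok] = s
    mu = np.exp(eta) * out["area_km2"].to_numpy(dtype=float)
    se_mu = mu * se_eta  # delta method on the log link
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = 100.0 * se_mu / mu
    out["pred_groups"] = mu
    out["se_groups"] = se_mu
    out["cv"] = cv
    return out


def mask_by_cv(cells: pd.DataFrame, threshold: float = 100.0) -> pd.DataFrame:
    """Retain cells with finite predictions and CV < threshold."""
    keep = np.isfinite(cells["pred_groups"]) & (cells["cv"] < threshold)
    return cells[keep].copy()


def _region_mask(cells: pd.DataFrame, sub_region) -> np.ndarray:
    if sub_region is None:
        return np.ones(len(cells), dtype=bool)
    from shapely.geometry import Point

    return np.array(
        [sub_region.contains(Point(x, y)) for x, y in zip(cells["x"], cells["y"])]
    )


def summarize_abundance(
    cells: pd.DataFrame,
    fit: DSMFit,
    group_size: GroupSizeEstimate | float,
    sub_region=None,
    ci: str = "normal",
) -> AbundanceEstimate:
    """Total abundance over the retained (CV-masked) cells.

    ``cells`` is the output of :func:`mask_by_cv`.  ``sub_region`` may
    be a shapely polygon selecting a hotspot; cell membership is by
    cell centre.  ``ci`` is "normal" (N +/- 1.96 SE) or "lognormal".
    """
    mask = _region_mask(cells, sub_region)
    sel = cells[mask]
    if len(sel) == 0:
        raise ValueError("no retained cells in the requested region")
    es = group_size.expected_size if isinstance(group_size, GroupSizeEstimate) else float(group_size)

    mu = sel["pred_groups"].to_numpy(dtype=float)
    N_groups = float(mu.sum())
    # full-covariance delta method: grad = sum_c mu_c * x_c
    X = fit.design(sel)
    grad = mu @ X
    var = float(grad @ fit.cov @ grad)
    se = float(np.sqrt(max(var, 0.0)))

    area = float(sel["area_km2"].sum())
    N_ind = N_groups * es
    if ci == "lognormal":
        cv2 = (se / N_groups) ** 2
        c = float(np.exp(1.96 * np.sqrt(np.log1p(cv2))))
        lo_g, hi_g = N_groups / c, N_groups * c
    else:
        lo_g = N_groups - 1.96 * se
        hi_g = N_groups + 1.96 * se
    lo_g = max(lo_g, 0.0)
    return AbundanceEstimate(
        area_km2=area,
        n_groups=N_groups,
        n_groups_se=se,
        n_individuals=N_ind,
        density_groups=N_groups / area,
        density_individuals=N_ind / area,
        ci95_groups=(lo_g, hi_g),
        ci95_individuals=(lo_g * es, hi_g * es),
        group_size_used=es,
    )
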