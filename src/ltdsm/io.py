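"""Readers, writers, configuration and the end-to-end pipeline.

CSV dialects (UTF-8, comma-separated, ISO-8601 timestamps):

* sightings: transect_id, datetime, declination_deg OR perp_distance_m,
  group_size, seastate, subjective, lat, lon (or projected x, y in km);
* effort: transect_id, datetime, lat, lon (or x, y), on_effort,
  seastate, subjective.  GPX 1.1 track files are also accepted for
  effort (one transect per track segment, always on-effort).

Rows failing validation are never silently dropped: readers return an
(accepted, rejected) pair where each rejected row carries its reason.

``run_pipeline`` chains the whole analysis: truncate -> fit all
candidate detection functions -> rank/select -> effective strip width
-> segmentise effort -> attach covariates -> fit candidate density
surface models -> rank/select -> grid prediction -> CV mask ->
abundance summary, writing the three report tables when asked.
"""

from __future__ import annotations

import json
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import segmentation, terrain
from .detection import (
    DetectionConfig,
    DetectionFit,
    expected_group_size,
    fit_detection,
    rank_detection_models,
)
from .dsm import DSMFit, SmootherSpec, SmoothTerm, fit_dsm, rank_dsm_models, select_best_dsm
from .prediction import make_grid, mask_by_cv, predict_cells, summarize_abundance
from .project import LocalAzimuthalEqualArea
from .raster import Raster

logger = logging.getLogger("ltdsm")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "read_sightings_csv",
    "read_effort_csv",
    "read_effort_gpx",
    "write_survey_csvs",
    "write_detection_table",
    "write_dsm_table",
    "write_abundance_table",
    "run_pipeline",
    "default_detection_candidates",
    "default_dsm_candidates",
]


# ---------------------------------------------------------------------------
# readers


def _project_latlon(df: pd.DataFrame, proj=None):
    if {"x", "y"}.issubset(df.columns):
        return df, proj
    if not {"lat", "lon"}.issubset(df.columns):
        raise ValueError("need either projected x/y (km) or lat/lon columns")
    if proj is None:
        proj = LocalAzimuthalEqualArea.centred_on(df["lon"], df["lat"])
    x, y = proj.forward(df["lon"].to_numpy(float), df["lat"].to_numpy(float))
    df = df.copy()
    df["x"] = x
    df["y"] = y
    return df, proj


def read_sightings_csv(path, altitude_m: float = 182.88, proj=None):
    """Read and validate sightings; returns (accepted, rejected, proj).

    Declination angles are converted to perpendicular distances with
    the platform altitude; a recorded ``perp_distance_m`` wins when
    both are present.
    """
    raw = pd.read_csv(path)
    for col in ("transect_id", "datetime", "group_size"):
        if col not in raw.columns:
            raise ValueError(f"sightings file is missing mandatory column {col!r}")
    if "perp_distance_m" not in raw.columns and "declination_deg" not in raw.columns:
        raise ValueError("sightings need perp_distance_m or declination_deg")
    accepted, rejected = [], []
    for i, row in raw.iterrows():
        reason = None
        ts = pd.to_datetime(row["datetime"], errors="coerce")
        if pd.isna(ts):
            reason = "unparseable timestamp"
        dist = row.get("perp_distance_m", np.nan)
        if reason is None and not np.isfinite(dist):
            dec = row.get("declination_deg", np.nan)
            if not np.isfinite(dec):
                reason = "no distance or declination"
            elif not (0 < dec <= 90):
                reason = "declination outside (0, 90]"
            else:
                dist = segmentation.declination_to_distance(dec, altitude_m)
        if reason is None and (not np.isfinite(dist) or dist < 0):
            reason = "invalid perpendicular distance"
        size = row.get("group_size", np.nan)
        if reason is None and (not np.isfinite(size) or size < 1 or size != int(size)):
            reason = "group_size must be an integer >= 1"
        if reason is None and str(row.get("subjective", "good")) not in (
            "good", "moderate", "poor",
        ):
            reason = "unknown subjective level"
        if reason:
            rejected.append({**row.to_dict(), "reject_reason": reason})
        else:
            accepted.append(
                {
                    "transect_id": row["transect_id"],
                    "timestamp": ts,
                    "perp_distance": float(dist),
                    "group_size": int(size),
                    "seastate": float(row.get("seastate", np.nan)),
                    "subjective": str(row.get("subjective", "good")),
                    "lat": row.get("lat", np.nan),
                    "lon": row.get("lon", np.nan),
                    "x": row.get("x", np.nan),
                    "y": row.get("y", np.nan),
                }
            )
    acc = pd.DataFrame(accepted)
    rej = pd.DataFrame(rejected)
    logger.info("sightings: %d accepted, %d rejected", len(acc), len(rej))
    if len(acc) and acc[["lat", "lon"]].notna().all(axis=None) and acc["x"].isna().all():
        acc, proj = _project_latlon(acc.drop(columns=["x", "y"]), proj)
    return acc, rej, proj


def read_effort_csv(path, proj=None):
    """Effort fixes from CSV; returns (track table, projection)."""
    raw = pd.read_csv(path)
    for col in ("transect_id", "datetime", "on_effort"):
        if col not in raw.columns:
            raise ValueError(f"effort file is missing mandatory column {col!r}")
    raw["timestamp"] = pd.to_datetime(raw["datetime"])
    raw["on_effort"] = raw["on_effort"].astype(bool)
    raw, proj = _project_latlon(raw, proj)
    cols = ["transect_id", "timestamp", "x", "y", "on_effort"]
    for extra in ("seastate", "subjective"):
        if extra in raw.columns:
            cols.append(extra)
    return raw[cols], proj


def read_effort_gpx(path, proj=None):
    """Effort fixes from a GPX 1.1 track file (always on-effort)."""
    ns = {"g": "http://www.topografix.com/GPX/1/1"}
    root = ET.parse(path).getroot()
    rows = []
    for ti, trk in enumerate(root.findall("g:trk", ns)):
        name_el = trk.find("g:name", ns)
        base = name_el.text if name_el is not None else f"trk{ti}"
        for si, seg in enumerate(trk.findall("g:trkseg", ns)):
            tid = f"{base}-{si}" if si else base
            for pt in seg.findall("g:trkpt", ns):
                t_el = pt.find("g:time", ns)
                rows.append(
                    {
                        "transect_id": tid,
                        "timestamp": pd.to_datetime(t_el.text) if t_el is not None else pd.NaT,
                        "lat": float(pt.get("lat")),
                        "lon": float(pt.get("lon")),
                        "on_effort": True,
                    }
                )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("GPX file contains no track points")
    df, proj = _project_latlon(df, proj)
    return df[["transect_id", "timestamp", "x", "y", "on_effort"]], proj


# ---------------------------------------------------------------------------
# writers


def write_survey_csvs(survey, out_dir):
    """Write a simulated survey in the pipeline's own CSV dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = survey.sightings.rename(
        columns={"timestamp": "datetime", "perp_distance": "perp_distance_m"}
    )
    s.to_csv(out / "sightings.csv", index=False)
    e = survey.effort.rename(columns={"timestamp": "datetime"})
    e.to_csv(out / "effort.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(survey.truth, fh, indent=2)
    return out / "sightings.csv", out / "effort.csv"


def write_detection_table(table: pd.DataFrame, path):
    out = table.rename(
        columns={
            "key": "Key", "adjustment": "Adj", "model": "Model",
            "covariates": "Covariates", "cvm_p": "CvM", "p0": "p0",
            "p0_se": "SE", "aic": "AIC", "delta_aic": "dAIC",
        }
    )[["Key", "Adj", "Model", "Covariates", "CvM", "p0", "SE", "AIC", "dAIC"]]
    out.to_csv(path, index=False)


def write_dsm_table(table: pd.DataFrame, path):
    out = table.rename(
        columns={
            "model": "Model", "covariates": "Covariates", "aic": "AIC",
            "gcv": "GCV", "delta_aic": "dAIC", "delta_gcv": "dGCV",
            "r2": "R2", "deviance_explained": "DevianceExplained",
        }
    )[["Model", "Covariates", "AIC", "GCV", "dAIC", "dGCV", "R2", "DevianceExplained"]]
    out.to_csv(path, index=False)


def write_abundance_table(estimates: dict, path):
    rows = []
    for name, est in estimates.items():
        rows.append(
            {
                "Region": name,
                "Area_km2": est.area_km2,
                "N": est.n_individuals,
                "CI_lo": est.ci95_individuals[0],
                "CI_hi": est.ci95_individuals[1],
                "D_groups": est.density_groups,
                "D_ind": est.density_individuals,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline


def default_detection_candidates(w: float = 1750.0) -> list[DetectionConfig]:
    """The standard candidate set: half-normal with/without cosine
    adjustment and covariates, hazard-rate with/without covariates."""
    return [
        DetectionConfig("half-normal", "cosine", (), w, label="c1"),
        DetectionConfig("half-normal", "cosine", ("seastate",), w, label="c2"),
        DetectionConfig("half-normal", "none", (), w, label="m1"),
        DetectionConfig("half-normal", "none", ("seastate",), w, label="m2"),
        DetectionConfig("hazard-rate", "none", (), w, label="h1"),
        DetectionConfig("hazard-rate", "none", ("seastate",), w, label="h2"),
    ]


def default_dsm_candidates(extra_covariates=()) -> list[SmootherSpec]:
    """s(x, y) alone and with one extra 1-D smooth per named covariate."""
    base = SmoothTerm(("mid_x", "mid_y"), k=30)
    cands = [SmootherSpec((base,), label="g1")]
    for i, cov in enumerate(extra_covariates, start=2):
        cands.append(SmootherSpec((base, SmoothTerm((cov,), k=10)), label=f"g{i}"))
    return cands


@dataclass
class PipelineConfig:
    truncation_w: float = 1750.0
    altitude_m: float = 182.88
    segment_target_km: float = 5.0
    segment_min_km: float = 1.0
    detection_candidates: list = field(default_factory=default_detection_candidates)
    exclude_hazard_rate: bool = False
    size_bias_alpha: float = 0.15
    dsm_candidates: list = field(default_factory=default_dsm_candidates)
    cell_km: float = 2.5
    cv_threshold: float = 100.0
    grid_extent: tuple | None = None  # (x_min, x_max, y_min, y_max)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {}
        simple = [
            "truncation_w", "altitude_m", "segment_target_km", "segment_min_km",
            "exclude_hazard_rate", "size_bias_alpha", "cell_km", "cv_threshold", "seed",
        ]
        for k in simple:
            if k in doc:
                kwargs[k] = doc[k]
        if "grid_extent" in doc:
            kwargs["grid_extent"] = tuple(doc["grid_extent"])
        w = kwargs.get("truncation_w", 1750.0)
        if "detection_candidates" in doc:
            kwargs["detection_candidates"] = [
                DetectionConfig(
                    c.get("key", "half-normal"), c.get("adjustment", "none"),
                    tuple(c.get("covariates", ())), w, label=c.get("label", ""),
                )
                for c in doc["detection_candidates"]
            ]
        if "dsm_candidates" in doc:
            kwargs["dsm_candidates"] = [
                SmootherSpec(
                    tuple(SmoothTerm(tuple(t["variables"]), t.get("k", 10)) for t in c["terms"]),
                    label=c.get("label", ""),
                )
                for c in doc["dsm_candidates"]
            ]
        return cls(**kwargs)


@dataclass
class PipelineResult:
    detection_table: pd.DataFrame
    detection_fit: DetectionFit
    esw_km: float
    group_size: object
    segments: pd.DataFrame
    dsm_table: pd.DataFrame
    dsm_fit: DSMFit
    cells: pd.DataFrame
    retained: pd.DataFrame
    estimate: object


def _attach_covariates(df: pd.DataFrame, covariates: dict, as_segments: bool) -> pd.DataFrame:
    out = df.copy()
    for name, source in covariates.items():
        if callable(source):
            out[name] = source(out["mid_x" if as_segments else "x"].to_numpy(float),
                               out["mid_y" if as_segments else "y"].to_numpy(float))
        elif isinstance(source, Raster):
            if as_segments:
                out[name] = [
                    terrain.average_along_segment(row, raster=source)
                    for _, row in out.iterrows()
                ]
            else:
                out[name] = source.sample_bilinear(out["x"].to_numpy(float),
                                                   out["y"].to_numpy(float))
        else:  # vector feature: distance covariate
            pts = (
                out[["mid_x", "mid_y"]] if as_segments else out[["x", "y"]]
            ).to_numpy(float)
            out[name] = terrain.distance_to_feature(pts, source)
    return out


def run_pipeline(
    sightings: pd.DataFrame,
    effort: pd.DataFrame,
    config: PipelineConfig,
    covariates: dict | None = None,
    out_dir=None,
) -> PipelineResult:
    """Run the full abundance-estimation chain on projected survey data.

    ``sightings``/``effort`` use the in-memory layouts produced by the
    readers or the simulator (projected x/y in km).  ``covariates``
    maps names to a Raster, a shapely feature (distance covariate) or a
    callable(x, y); they are averaged along segments and evaluated at
    grid-cell centres.
    """
    covariates = covariates or {}

    # --- detection
    fits = []
    for cand in config.detection_candidates:
        try:
            fits.append(fit_detection(sightings, cand))
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"detection candidate {cand.label or cand.key}: {err}")
    if not fits:
        raise RuntimeError("pipeline aborted at stage 'detection': no candidate converged")
    det_table = rank_detection_models(fits)
    logger.info("detection: %d candidates fitted on n = %d", len(fits), fits[0].n_used)
    pool = [f for f in fits if not (config.exclude_hazard_rate and f.config.key == "hazard-rate")]
    best_det = min(pool, key=lambda f: f.aic)
    esw_km = best_det.esw / 1000.0
    gs = expected_group_size(sightings, best_det, alpha=config.size_bias_alpha)

    # --- segmentation
    segs = segmentation.split_effort(effort, config.segment_target_km, config.segment_min_km)
    if segs.empty:
        raise RuntimeError("pipeline aborted at stage 'segmentation': no usable segments")
    segs = segmentation.assign_sightings(segs, sightings, config.truncation_w)
    segs["effective_area"] = segmentation.effective_area(segs["length_km"], esw_km)
    segs = _attach_covariates(segs, covariates, as_segments=True)
    logger.info("segmentation: %d segments, %d groups assigned", len(segs), segs["n_groups"].sum())

    # --- density surface model
    dsm_fits = []
    for spec in config.dsm_candidates:
        try:
            dsm_fits.append(fit_dsm(segs, spec))
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"dsm candidate {spec.label or spec.formula}: {err}")
    if not dsm_fits:
        raise RuntimeError("pipeline aborted at stage 'dsm': no candidate converged")
    dsm_table = rank_dsm_models(dsm_fits)
    best_dsm = select_best_dsm(dsm_fits)
    logger.info("dsm: selected %s (power %.2f)", best_dsm.spec.label or best_dsm.spec.formula,
                best_dsm.power)

    # --- prediction
    if config.grid_extent is not None:
        x0, x1, y0, y1 = config.grid_extent
    else:
        x0, x1 = effort["x"].min(), effort["x"].max()
        y0, y1 = effort["y"].min(), effort["y"].max()
    grid = make_grid(x0, x1, y0, y1, config.cell_km)
    # grid cells expose the same coordinate names the smooths were built on
    grid["mid_x"] = grid["x"]
    grid["mid_y"] = grid["y"]
    grid = _attach_covariates(grid, covariates, as_segments=False)
    cells = predict_cells(best_dsm, grid)
    retained = mask_by_cv(cells, config.cv_threshold)
    if retained.empty:
        raise RuntimeError(
            "pipeline aborted at stage 'prediction': no cell passed the CV mask"
        )
    est = summarize_abundance(retained, best_dsm, gs)
    logger.info("prediction: %d/%d cells retained, N = %.1f individuals",
                len(retained), len(cells), est.n_individuals)

    result = PipelineResult(
        detection_table=det_table,
        detection_fit=best_det,
        esw_km=esw_km,
        group_size=gs,
        segments=segs,
        dsm_table=dsm_table,
        dsm_fit=best_dsm,
        cells=cells,
        retained=retained,
        estimate=est,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_detection_table(det_table, out / "detection_models.csv")
        write_dsm_table(dsm_table, out / "dsm_models.csv")
        write_abundance_table({"prediction_area": est}, out / "abundance.csv")
        segs.to_csv(out / "segments.csv", index=False)
        cells.to_csv(out / "prediction_cells.csv", index=False)
    return result
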