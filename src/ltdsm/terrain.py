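"""Terrain covariates from a bathymetry raster and vector features.

Derives, on the 3x3 neighbourhood of each interior cell:

* TPI (topographic position index): centre minus the mean of the eight
  neighbours — positive on ridges/banks, negative in depressions;
* TRI (terrain ruggedness index): mean absolute difference between the
  centre and its eight neighbours;
* slope and aspect by Horn's weighted finite differences; aspect is
  degrees clockwise from north (downslope direction), no-data on flat
  cells.

Edges are no-data.  Depth is negative below sea level and used as-is.
Distances from points to the shelf break / coastline polylines are
Euclidean in the projected plane (km).
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import MultiLineString, Point
from shapely.ops import unary_union

from .raster import Raster

__all__ = ["terrain_metrics", "distance_to_feature", "average_along_segment"]


def _neighbour_stack(z: np.ndarray) -> np.ndarray:
    """(8, nr-2, nc-2) stack of the eight neighbours of interior cells."""
    return np.stack(
        [
            z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:],
            z[1:-1, :-2], z[1:-1, 2:],
            z[2:, :-2], z[2:, 1:-1], z[2:, 2:],
        ]
    )


def terrain_metrics(depth: Raster) -> dict[str, Raster]:
    """TPI, TRI, slope (degrees) and aspect (degrees) from a depth grid."""
    z = depth.data
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("raster must be at least 3x3")
    if not np.any(np.isfinite(z)):
        raise ValueError("raster is entirely no-data")
    nr, nc = z.shape
    centre = z[1:-1, 1:-1]
    nb = _neighbour_stack(z)

    tpi = centre - nb.mean(axis=0)
    tri = np.abs(centre - nb).mean(axis=0)

    # Horn's method; rows run north -> south
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    cs = depth.cellsize
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cs)
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * cs)  # y increases north
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # downslope azimuth clockwise from north; flat -> no-data
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect = np.where(slope > 0, aspect, np.nan)

    out = {}
    for name, interior in (("TPI", tpi), ("TRI", tri), ("slope", slope), ("aspect", aspect)):
        grid = np.full((nr, nc), np.nan)
        grid[1:-1, 1:-1] = interior
        out[name] = Raster(grid, depth.xll, depth.yll, depth.cellsize, name=name)
    return out


def distance_to_feature(points, feature) -> np.ndarray:
    """Euclidean distance (projected km) to the nearest point on any polyline.

    ``points`` is an (n, 2) array; ``feature`` a shapely geometry or an
    iterable of coordinate sequences making up polylines.
    """
    if feature is None:
        raise ValueError("feature geometry is empty")
    if not hasattr(feature, "distance"):
        lines = [np.asarray(part, dtype=float) for part in feature]
        if not lines:
            raise ValueError("feature geometry is empty")
        feature = unary_union(MultiLineString([[tuple(p) for p in ln] for ln in lines]))
    if feature.is_empty:
        raise ValueError("feature geometry is empty")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.array([feature.distance(Point(px, py)) for px, py in pts])


def _segment_sample_points(segment, step_km: float = 0.5) -> np.ndarray:
    """Points at ``step_km`` intervals along the segment chord (incl. ends)."""
    p0 = np.array([segment["x_start"], segment["y_start"]], dtype=float)
    p1 = np.array([segment["x_end"], segment["y_end"]], dtype=float)
    length = float(segment["length_km"])
    n = max(int(np.floor(length / step_km)), 1)
    ts = np.linspace(0.0, 1.0, n + 1)
    return p0[None, :] + ts[:, None] * (p1 - p0)[None, :]


def average_along_segment(
    segment, raster: Raster | None = None, feature=None, step_km: float = 0.5
) -> float:
    """Mean covariate value sampled along one segment.

    Samples at ``step_km`` intervals along the segment; raster values by
    bilinear interpolation with no-data samples excluded, feature values
    as distance-to-feature.  Returns NaN when every sample is no-data
    (the segment is then flagged for model-specific exclusion upstream).
    """
    pts = _segment_sample_points(segment, step_km)
    if raster is not None:
        vals = np.atleast_1d(raster.sample_bilinear(pts[:, 0], pts[:, 1]))
    elif feature is not None:
        vals = distance_to_feature(pts, feature)
    else:
        raise ValueError("provide a raster or a feature")
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")
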