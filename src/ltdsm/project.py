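"""Local map projection for survey coordinates.

A spherical Lambert azimuthal equal-area projection centred on the data
(or on an explicit centre) maps longitude/latitude onto planar x, y in
kilometres.  Over a survey-sized domain (a few hundred km) the equal-
area property keeps segment lengths and cell areas faithful, which is
what the effort bookkeeping and density arithmetic require.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


class LocalAzimuthalEqualArea:
    """Forward/inverse spherical Lambert azimuthal equal-area projection."""

    def __init__(self, lon0: float, lat0: float, radius_km: float = EARTH_RADIUS_KM):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.R = float(radius_km)

    @classmethod
    def centred_on(cls, lon, lat) -> "LocalAzimuthalEqualArea":
        """Projection centred on the bounding box of the given points."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return cls(0.5 * (lon.min() + lon.max()), 0.5 * (lat.min() + lat.max()))

    def forward(self, lon, lat):
        """(lon, lat) degrees -> (x, y) km."""
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        lam0 = np.radians(self.lon0)
        phi0 = np.radians(self.lat0)
        dlam = lam - lam0
        cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
        # k' = sqrt(2 / (1 + cos c)); antipode excluded by construction
        kp = np.sqrt(2.0 / np.clip(1.0 + cosc, 1e-12, None))
        x = self.R * kp * np.cos(phi) * np.sin(dlam)
        y = self.R * kp * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam)
        )
        return x, y

    def inverse(self, x, y):
        """(x, y) km -> (lon, lat) degrees."""
        x = np.asarray(x, dtype=float) / self.R
        y = np.asarray(y, dtype=float) / self.R
        rho = np.sqrt(x * x + y * y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        phi0 = np.radians(self.lat0)
        with np.errstate(invalid="ignore"):
            phi = np.where(
                rho > 0,
                np.arcsin(
                    np.cos(c) * np.sin(phi0)
                    + np.where(rho > 0, y * np.sin(c) / np.where(rho > 0, rho, 1.0), 0.0)
                    * np.cos(phi0)
                ),
                phi0,
            )
            lam = np.radians(self.lon0) + np.arctan2(
                x * np.sin(c),
                rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
            )
        return np.degrees(lam), np.degrees(phi)
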