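"""Local azimuthal-equidistant projection on a sphere.

All simulation and analysis happens on a plane centred on the colony, in km.
Distances from the centre are exact great-circle distances, which is the
property the movement model needs (step lengths in km are well defined).
Formulas follow Snyder's "Map Projections — A Working Manual".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class AzimuthalEquidistant:
    """Forward/inverse azimuthal-equidistant projection centred on (lon0, lat0).

    Forward maps WGS84-style lon/lat degrees to (x, y) in km with x east and
    y north; inverse maps back.  Spherical earth, radius 6371.0088 km.
    """

    lon0: float
    lat0: float
    radius_km: float = EARTH_RADIUS_KM

    def forward(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lam, phi = np.radians(lon), np.radians(lat)
        lam0, phi0 = np.radians(self.lon0), np.radians(self.lat0)
        dlam = lam - lam0
        cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k = c / sin(c), with the c -> 0 limit k = 1
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = self.radius_km * k * np.cos(phi) * np.sin(dlam)
        y = self.radius_km * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam)
        )
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        phi0 = np.radians(self.lat0)
        lam0 = np.radians(self.lon0)
        rho = np.hypot(x, y)
        c = rho / self.radius_km
        sin_c, cos_c = np.sin(c), np.cos(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            safe_rho = np.where(rho > 1e-12, rho, 1.0)
            phi = np.arcsin(
                np.clip(cos_c * np.sin(phi0) + y * sin_c * np.cos(phi0) / safe_rho, -1, 1)
            )
            lam = lam0 + np.arctan2(
                x * sin_c, safe_rho * cos_c * np.cos(phi0) - y * sin_c * np.sin(phi0)
            )
        phi = np.where(rho > 1e-12, phi, phi0)
        lam = np.where(rho > 1e-12, lam, lam0)
        lon = np.degrees(lam)
        lon = (lon + 180.0) % 360.0 - 180.0
        return lon, np.degrees(phi)
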