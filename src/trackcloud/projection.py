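"""Lambert azimuthal equal-area projection for North Pacific track data.

All analyses in this package run on a projected plane in kilometres.
Occupancy and density statistics count equal-area grid cells, so the
projection must preserve area; and the study region straddles the
antimeridian, so longitudes are normalized to [0, 360) before projection
and the projection is centered inside the region (57° N, 190° E) where
distortion is smallest.

Spherical closed-form equations (Snyder, *Map Projections — A Working
Manual*, USGS PP 1395, eqs. 24-2 … 24-4 and 20-14 … 20-18).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088
CENTER_LAT = 57.0
CENTER_LON = 190.0


def project(lon, lat, center_lon: float = CENTER_LON, center_lat: float = CENTER_LAT,
            radius: float = EARTH_RADIUS_KM):
    """Forward projection: geographic degrees -> planar km.

    Parameters
    ----------
    lon, lat : array_like
        Longitude (any convention; normalized to [0, 360)) and latitude
        in degrees.

    Returns
    -------
    x, y : ndarray
        Easting and northing in km relative to the projection center.
    """
    lon = np.mod(np.asarray(lon, dtype=float), 360.0)
    lat = np.asarray(lat, dtype=float)
    lam = np.radians(lon - center_lon)
    phi = np.radians(lat)
    phi0 = np.radians(center_lat)

    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
    k = np.sqrt(2.0 / denom)
    x = radius * k * np.cos(phi) * np.sin(lam)
    y = radius * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam))
    return x, y


def unproject(x, y, center_lon: float = CENTER_LON, center_lat: float = CENTER_LAT,
              radius: float = EARTH_RADIUS_KM):
    """Inverse projection: planar km -> (lon in [0, 360), lat) degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    phi0 = np.radians(center_lat)

    rho = np.hypot(x, y)
    # clip guards rounding at the projection limit rho = 2R
    c = 2.0 * np.arcsin(np.clip(rho / (2.0 * radius), -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.arcsin(np.clip(
            np.cos(c) * np.sin(phi0) + np.where(rho > 0, y * np.sin(c) * np.cos(phi0) / rho, 0.0),
            -1.0, 1.0))
        lam = np.arctan2(x * np.sin(c),
                         rho * np.cos(c) * np.cos(phi0) - y * np.sin(c) * np.sin(phi0))
    phi = np.where(rho == 0, phi0, phi)
    lam = np.where(rho == 0, 0.0, lam)
    lon = np.mod(center_lon + np.degrees(lam), 360.0)
    return lon, np.degrees(phi)
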