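"""Spherical-earth distance, projection and cell-area helpers.

All geographic coordinates are WGS84 decimal degrees (lon, lat).  Metric
computations use a spherical earth of mean radius 6371.0088 km; at the
spatial scales this package targets (tens of kilometres) the departure from
an ellipsoidal model is far below the other sources of uncertainty in a
distribution model.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as _shapely_transform

EARTH_RADIUS_KM = 6371.0088
#: kilometres per degree of longitude at the equator (spherical-degree constant)
KM_PER_DEG_LON_EQUATOR = 111.320
#: kilometres per degree of latitude (spherical-degree constant)
KM_PER_DEG_LAT = 110.574


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_distance_km(lons, lats) -> np.ndarray:
    """Full symmetric matrix of great-circle distances (km)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def aeqd_forward(lon, lat, lon0: float, lat0: float):
    """Azimuthal equidistant projection (spherical), centred at (lon0, lat0).

    Returns (x, y) in kilometres.  Distances from the centre are exact on the
    sphere, which is why buffers of a stated radius are constructed in this
    projection.
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    dlon = lon - lam0
    cosc = np.sin(phi0) * np.sin(lat) + np.cos(phi0) * np.cos(lat) * np.cos(dlon)
    c = np.arccos(np.clip(cosc, -1.0, 1.0))
    # k = c / sin(c), with the removable singularity at c == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlon)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(lat)
                               - np.sin(phi0) * np.cos(lat) * np.cos(dlon))
    return x, y


def aeqd_inverse(x, y, lon0: float, lat0: float):
    """Inverse of :func:`aeqd_forward`; (x, y) in km -> (lon, lat) degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_KM
    sinc, cosc = np.sin(c), np.cos(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        lat = np.where(
            rho > 1e-12,
            np.arcsin(np.clip(cosc * math.sin(phi0)
                              + np.where(rho > 1e-12, y * sinc / np.where(rho > 1e-12, rho, 1.0), 0.0)
                              * math.cos(phi0), -1.0, 1.0)),
            phi0,
        )
        lon = np.where(
            rho > 1e-12,
            lam0 + np.arctan2(x * sinc,
                              rho * math.cos(phi0) * cosc - y * math.sin(phi0) * sinc),
            lam0,
        )
    return np.degrees(lon), np.degrees(lat)


def laea_forward(lon, lat, lon0: float, lat0: float):
    """Lambert azimuthal equal-area projection (spherical), km units.

    Preserves area, hence used for convex-hull (EOO) and grid-cell (AOO)
    area accounting.
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    lam0, phi0 = math.radians(lon0), math.radians(lat0)
    dlon = lon - lam0
    denom = 1.0 + np.sin(phi0) * np.sin(lat) + np.cos(phi0) * np.cos(lat) * np.cos(dlon)
    denom = np.maximum(denom, 1e-12)  # antipode guard
    k = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlon)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(lat)
                               - np.sin(phi0) * np.cos(lat) * np.cos(dlon))
    return x, y


def project_geometry(geom: BaseGeometry,
                     forward: Callable) -> BaseGeometry:
    """Apply a (lon, lat) -> (x, y) coordinate transform to a shapely geometry."""
    return _shapely_transform(lambda xx, yy, zz=None: forward(xx, yy), geom)


def cell_area_km2(cell_width_deg: float, cell_height_deg: float, lat_center) -> np.ndarray:
    """Approximate area of a geographic grid cell centred at latitude ``lat_center``.

    Uses the fixed spherical-degree constants 111.320 km/deg (longitude at the
    equator, scaled by cos latitude) and 110.574 km/deg (latitude).
    """
    lat = np.radians(np.asarray(lat_center, dtype=float))
    w = cell_width_deg * KM_PER_DEG_LON_EQUATOR * np.cos(lat)
    h = cell_height_deg * KM_PER_DEG_LAT
    return w * h
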