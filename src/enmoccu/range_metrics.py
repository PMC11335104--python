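"""IUCN-style range comparators: extent of occurrence and area of occupancy.

EOO is the area of the convex hull of the records; AOO counts occupied
cells of a fixed grid (IUCN default 2 x 2 km).  Both are computed in a
Lambert azimuthal equal-area projection centred on the record centroid; the
AOO grid is anchored at the projected origin (a fixed, deterministic
anchoring rather than the IUCN-permitted minimizing shift).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint

from .geodesy import laea_forward
from .prep import OccurrenceSet


@dataclass
class RangeSummary:
    eoo_km2: float
    aoo_km2: float
    aoo_cell_km: float
    n_points: int


def _project(occ: OccurrenceSet) -> tuple[np.ndarray, np.ndarray]:
    lon0 = float(np.mean(occ.lons))
    lat0 = float(np.mean(occ.lats))
    return laea_forward(occ.lons, occ.lats, lon0, lat0)


def eoo(occ: OccurrenceSet) -> float:
    """Extent of occurrence: convex-hull area (km^2) in a local equal-area
    projection.  Fewer than 3 distinct non-collinear points give 0 with a
    warning."""
    if len(occ) < 3:
        warnings.warn("fewer than 3 points: EOO is 0")
        return 0.0
    x, y = _project(occ)
    hull = MultiPoint(list(zip(x, y))).convex_hull
    if hull.geom_type != "Polygon":
        warnings.warn("collinear points: EOO is 0")
        return 0.0
    return float(hull.area)


def aoo(occ: OccurrenceSet, cell_km: float = 2.0) -> float:
    """Area of occupancy: number of distinct ``cell_km``-sized grid cells
    (grid anchored at the projected origin) containing at least one record,
    times the cell area."""
    if len(occ) < 1:
        raise ValueError("need at least one point")
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    x, y = _project(occ)
    cells = set(zip(np.floor(x / cell_km).astype(int),
                    np.floor(y / cell_km).astype(int)))
    return float(len(cells)) * cell_km ** 2


def range_summary(occ: OccurrenceSet, cell_km: float = 2.0) -> RangeSummary:
    return RangeSummary(eoo_km2=eoo(occ), aoo_km2=aoo(occ, cell_km),
                        aoo_cell_km=cell_km, n_points=len(occ))
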