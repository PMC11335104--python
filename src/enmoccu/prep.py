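"""Occurrence and covariate preparation for niche-model calibration.

Covers the steps that turn raw point records and raw rasters into
calibration-ready inputs: spatial thinning, construction of the accessible
area M (buffered minimum convex polygon intersected with a region polygon),
and Spearman-based collinearity filtering into one or more variable sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from shapely.geometry import MultiPoint, Point
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .geodesy import aeqd_forward, aeqd_inverse, pairwise_distance_km, project_geometry
from .raster import EnvStack

VALID_SOURCES = {"collection", "community", "field", "synthetic"}


@dataclass
class OccurrenceSet:
    """Point records (id, lon, lat, source) in WGS84 decimal degrees."""

    df: pd.DataFrame

    def __post_init__(self):
        required = {"id", "lon", "lat", "source"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
        df = self.df.reset_index(drop=True)
        if df["id"].duplicated().any():
            raise ValueError("occurrence ids must be unique")
        if ((df["lon"] < -180) | (df["lon"] > 180)).any():
            raise ValueError("longitude out of [-180, 180]")
        if ((df["lat"] < -90) | (df["lat"] > 90)).any():
            raise ValueError("latitude out of [-90, 90]")
        bad = set(df["source"]) - VALID_SOURCES
        if bad:
            raise ValueError(f"unknown source tags: {sorted(bad)}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lons(self) -> np.ndarray:
        return self.df["lon"].to_numpy(dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return self.df["lat"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))


@dataclass
class CalibrationArea:
    """The accessible area M: a (multi)polygon in WGS84 degrees."""

    polygon: BaseGeometry
    name: str = "M"

    def __post_init__(self):
        if self.polygon.is_empty:
            raise ValueError("calibration area polygon is empty")
        if not self.polygon.is_valid:
            self.polygon = make_valid(self.polygon)


def thin_occurrences(occ: OccurrenceSet, min_dist_km: float) -> OccurrenceSet:
    """Greedy spatial thinning: keep a record iff it is at least
    ``min_dist_km`` (great-circle) from every already-kept record, scanning
    in input order.  Deterministic; output is a subset of the input.
    """
    if min_dist_km <= 0:
        raise ValueError("min_dist_km must be positive")
    n = len(occ)
    if n == 0:
        return OccurrenceSet(occ.df.iloc[:0].copy())
    dist = pairwise_distance_km(occ.lons, occ.lats)
    kept: list[int] = []
    for i in range(n):
        if all(dist[i, j] >= min_dist_km for j in kept):
            kept.append(i)
    return OccurrenceSet(occ.df.iloc[kept].reset_index(drop=True))


def build_accessible_area(occ: OccurrenceSet, buffer_km: float,
                          regions: CalibrationArea) -> CalibrationArea:
    """Accessible area M = convex hull of ``buffer_km`` buffers around every
    record, intersected with the supplied region polygon.

    Buffers and the hull are built in an azimuthal-equidistant projection
    centred on the record centroid (metric fidelity at the ~50 km scale),
    then mapped back to geographic coordinates.
    """
    if buffer_km <= 0:
        raise ValueError("buffer_km must be positive")
    if len(occ) < 3:
        raise ValueError("need at least 3 records to build an accessible area")
    lon0 = float(np.mean(occ.lons))
    lat0 = float(np.mean(occ.lats))

    def fwd(lon, lat):
        return aeqd_forward(lon, lat, lon0, lat0)

    def inv(x, y):
        return aeqd_inverse(x, y, lon0, lat0)

    x, y = fwd(occ.lons, occ.lats)
    discs = [Point(xi, yi).buffer(buffer_km, quad_segs=64) for xi, yi in zip(x, y)]
    hull = MultiPoint([p for d in discs for p in d.exterior.coords]).convex_hull
    regions_proj = project_geometry(regions.polygon, fwd)
    m_proj = hull.intersection(regions_proj)
    if m_proj.is_empty:
        raise ValueError(
            f"accessible area is empty: buffered hull (bounds {hull.bounds}) does not "
            f"intersect region polygon {regions.name!r} (bounds {regions_proj.bounds})")
    m_geo = project_geometry(m_proj, inv)
    return CalibrationArea(make_valid(m_geo), name="M")


def spearman_matrix(stack: EnvStack, mask: np.ndarray | None = None) -> pd.DataFrame:
    """Pairwise Spearman rank correlations over valid (optionally masked) cells."""
    valid = ~stack.nodata_mask
    if mask is not None:
        valid = valid & mask
    if not valid.any():
        raise ValueError("no valid cells to correlate (area entirely nodata)")
    data = np.column_stack([stack.layers[n][valid] for n in stack.names])
    if data.shape[1] == 1:
        rho = np.ones((1, 1))
    elif data.shape[1] == 2:
        r = spearmanr(data[:, 0], data[:, 1]).statistic
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.atleast_2d(spearmanr(data).statistic)
    return pd.DataFrame(rho, index=stack.names, columns=stack.names)


def correlation_filter(stack: EnvStack, area: "CalibrationArea | None" = None,
                       threshold: float = 0.8,
                       mask: np.ndarray | None = None
                       ) -> tuple[EnvStack, pd.DataFrame]:
    """Drop layers until every retained pair has \\|Spearman rho\\| < threshold.

    Greedy with input-order priority: walk the layers in order, keeping a
    layer iff its correlation with every already-kept layer is below the
    threshold.  Returns the filtered stack and the full correlation matrix.
    """
    if stack.n_layers < 2:
        raise ValueError("need at least two layers to filter")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if area is not None and mask is None:
        from .raster import mask_from_polygon
        mask = mask_from_polygon(stack.transform, area.polygon)
    corr = spearman_matrix(stack, mask)
    kept: list[str] = []
    for name in stack.names:
        if all(abs(corr.loc[name, k]) < threshold for k in kept):
            kept.append(name)
    return stack.subset(kept), corr


def build_variable_sets(stack: EnvStack,
                        set_definitions: Mapping[str, Sequence[str]],
                        threshold: float = 0.8,
                        auto_filter: bool = False,
                        mask: np.ndarray | None = None) -> list[EnvStack]:
    """Slice a stack into named variable sets, each internally uncorrelated.

    With ``auto_filter`` the collinearity filter is applied inside each set;
    otherwise a correlated pair inside a set raises.
    """
    out: list[EnvStack] = []
    for set_id, names in set_definitions.items():
        names = list(names)
        if not names:
            raise ValueError(f"variable set {set_id!r} is empty")
        missing = [n for n in names if n not in stack.layers]
        if missing:
            raise KeyError(f"variable set {set_id!r} names missing layers: {missing}")
        sub = stack.subset(names, set_id=set_id)
        if sub.n_layers >= 2:
            corr = spearman_matrix(sub, mask)
            off = corr.to_numpy()[~np.eye(sub.n_layers, dtype=bool)]
            if np.any(np.abs(off) >= threshold):
                if auto_filter:
                    sub, _ = correlation_filter(sub, threshold=threshold, mask=mask)
                    sub.set_id = set_id
                else:
                    raise ValueError(
                        f"variable set {set_id!r} contains a pair with |rho| >= {threshold}")
        out.append(sub)
    return out
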