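"""Fusing the binary niche map with fine-scale occupancy predictions.

The coarse presence/absence niche map marks where macro conditions are
suitable; the best occupancy model is projected inside those cells at a
finer resolution (default 0.00025 degrees, roughly 27 m), and the resulting
occupancy surface is binarized at its own third quartile (Q3).  Cells
passing both filters constitute the realized distribution, whose area is
accounted with latitude-dependent spherical-degree cell areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .evaluation import BinaryMap
from .geodesy import cell_area_km2
from .occupancy import OccupancyResults
from .raster import EnvStack, GridTransform

FINE_CELL_SIZE_DEG = 0.00025


def project_occupancy(fit: OccupancyResults, fine_covariates: EnvStack) -> np.ndarray:
    """Cell-wise occupancy probability from a fitted model over a fine-scale
    covariate stack (layers in natural units; the fit's standardization
    record is applied).  Nodata propagates as NaN."""
    names = fit.model.psi_covariates
    missing = [n for n in names if n not in fine_covariates.layers]
    if missing:
        raise KeyError(f"fine covariate stack lacks layer(s): {missing}")
    eta = np.full(fine_covariates.shape, fit.beta_psi[0], dtype=float)
    for k, name in enumerate(names):
        v = fine_covariates.layers[name]
        if name in fit.model.data.standardization:
            v = fit.model.data.standardize_value(name, v)
        eta = eta + fit.beta_psi[1 + k] * v
    psi = expit(eta)
    psi[fine_covariates.nodata_mask] = np.nan
    return psi


def mask_and_refine(coarse: BinaryMap, fine_psi: np.ndarray,
                    fine_transform: GridTransform) -> np.ndarray:
    """Keep a fine cell iff the coarse binary cell containing its centre is
    presence (1); everything else becomes nodata (NaN)."""
    if coarse.transform is None:
        raise ValueError("coarse map lacks a geo transform")
    fine_psi = np.asarray(fine_psi, dtype=float)
    if fine_psi.shape != fine_transform.shape:
        raise ValueError("fine grid shape does not match its transform")
    lon, lat = fine_transform.center_grids()
    row, col = coarse.transform.rowcol(lon, lat)
    inside = coarse.transform.contains_rowcol(row, col)
    if not inside.any():
        raise ValueError("fine and coarse extents are disjoint")
    keep = np.zeros(fine_transform.shape, dtype=bool)
    rr = np.clip(row, 0, coarse.transform.n_rows - 1)
    cc = np.clip(col, 0, coarse.transform.n_cols - 1)
    keep[inside] = coarse.grid[rr[inside], cc[inside]] == 1.0
    out = np.where(keep, fine_psi, np.nan)
    return out


@dataclass
class RealizedDistribution:
    """Fine-resolution binary realized-distribution map with provenance."""

    grid: np.ndarray
    transform: GridTransform
    threshold: float
    area_km2: float
    provenance: tuple[str, ...] = ()


def area_km2(binary_grid: np.ndarray, transform: GridTransform) -> float:
    """Total area of presence (1) cells, summing per-cell spherical-degree
    areas (111.320 km/deg longitude at the equator scaled by cos latitude;
    110.574 km/deg latitude)."""
    grid = np.asarray(binary_grid, dtype=float)
    ones_per_row = np.nansum(grid == 1.0, axis=1).astype(float)
    row_area = cell_area_km2(transform.cell_size, transform.cell_size,
                             transform.lat_centers())
    return float(np.sum(ones_per_row * row_area))


def q3_binarize(masked_psi: np.ndarray, transform: GridTransform,
                quantile: float = 0.75,
                provenance: tuple[str, ...] = ()) -> RealizedDistribution:
    """Binarize a masked occupancy surface at its own Q3 (linear-interpolation
    quantile over non-nodata cells); ties at the threshold count as
    presence."""
    masked_psi = np.asarray(masked_psi, dtype=float)
    valid = np.isfinite(masked_psi)
    if valid.sum() < 4:
        raise ValueError("need at least 4 non-nodata cells for a quartile")
    thr = float(np.quantile(masked_psi[valid], quantile))
    if np.ptp(masked_psi[valid]) == 0:
        warnings.warn("constant occupancy surface: threshold is degenerate, "
                      "all cells tie")
    grid = np.where(valid, (masked_psi >= thr).astype(float), np.nan)
    return RealizedDistribution(grid, transform, thr,
                                area_km2(grid, transform), provenance)


def veg_height_at_threshold(fit: OccupancyResults, threshold: float,
                            covariate: str = "Veg_H") -> float:
    """Invert a one-covariate occupancy model: the natural-unit covariate
    value whose predicted occupancy equals the threshold (cross-check for
    quantile-based cutoffs)."""
    from scipy.special import logit
    names = fit.model.psi_covariates
    if covariate not in names:
        raise KeyError(f"{covariate!r} is not an occupancy covariate of the fit")
    k = names.index(covariate)
    slope = fit.beta_psi[1 + k]
    if slope == 0:
        raise ValueError("zero slope: threshold does not map to a covariate value")
    z = (logit(threshold) - fit.beta_psi[0]) / slope
    if covariate in fit.model.data.standardization:
        return float(fit.model.data.destandardize(covariate, z))
    return float(z)
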