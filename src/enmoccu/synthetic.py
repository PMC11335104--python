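"""Synthetic landscapes, biased occurrences and detection histories.

Every downstream stage of the pipeline is exercised against data generated
here with known ground truth: spatially autocorrelated covariate rasters
(including a designated highly correlated layer pair, mimicking ground-level
versus atmospheric temperature measurements of the same quantity),
presence-only occurrences sampled from a known Gibbs suitability surface
with an optional smooth accessibility bias, and Bernoulli detection
histories from logit-linear occupancy and detection models with a stated
missing-survey fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .occupancy import DetectionData
from .prep import OccurrenceSet
from .raster import EnvStack, GridTransform


@dataclass
class LandscapeSpec:
    """Recipe for a synthetic covariate landscape.

    ``autocorr_range`` is the Gaussian smoothing length in cells (larger =
    smoother fields); ``correlated_pair`` designates the two layers mixed to
    the target Pearson correlation ``correlated_pair_rho``.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 0.01             # degrees per cell (~1.1 km)
    origin: tuple[float, float] = (-76.0, 7.0)   # (lon, lat) upper-left corner
    autocorr_range: float = 5.0         # correlation length, cells
    n_layers: int = 4
    correlated_pair: tuple[int, int] = (0, 1)
    correlated_pair_rho: float = 0.92
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("landscape needs at least 10 x 10 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not (-1.0 <= self.correlated_pair_rho <= 1.0):
            raise ValueError("correlated_pair_rho must be in [-1, 1]")
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        a, b = self.correlated_pair
        if self.n_layers >= 2 and (a == b or not (0 <= a < self.n_layers)
                                   or not (0 <= b < self.n_layers)):
            raise ValueError("correlated_pair must name two distinct layers")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(origin_lon=self.origin[0], origin_lat=self.origin[1],
                             cell_size=self.cell_size, n_rows=self.n_rows,
                             n_cols=self.n_cols)


@dataclass
class TruthParams:
    """Data-generating parameters: Gibbs feature weights for the suitability
    surface, and logit-scale occupancy/detection coefficient vectors
    (intercept first)."""

    lambda_true: np.ndarray = field(default_factory=lambda: np.zeros(4))
    beta_psi_true: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    alpha_p_true: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    missing_fraction: float = 0.0

    def __post_init__(self):
        self.lambda_true = np.asarray(self.lambda_true, dtype=float)
        self.beta_psi_true = np.asarray(self.beta_psi_true, dtype=float)
        self.alpha_p_true = np.asarray(self.alpha_p_true, dtype=float)
        for v in (self.lambda_true, self.beta_psi_true, self.alpha_p_true):
            if not np.isfinite(v).all():
                raise ValueError("truth coefficient vectors must be finite")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  autocorr_range: float) -> np.ndarray:
    """Standardized Gaussian random field: white noise convolved with a
    Gaussian kernel of width ``autocorr_range`` cells."""
    noise = rng.standard_normal(shape)
    if autocorr_range > 0:
        f = gaussian_filter(noise, sigma=autocorr_range, mode="reflect")
    else:
        f = noise
    return (f - f.mean()) / f.std()


def generate_env_stack(spec: LandscapeSpec) -> EnvStack:
    """Generate ``n_layers`` aligned standardized Gaussian-random-field
    layers; the designated pair is mixed to the target correlation
    (layer_b = rho * layer_a + sqrt(1 - rho^2) * independent field)."""
    if spec.autocorr_range >= min(spec.n_rows, spec.n_cols):
        raise ValueError("autocorr_range >= grid size: field would be constant")
    rng = np.random.default_rng(spec.seed)
    fields = [_smooth_field(rng, (spec.n_rows, spec.n_cols), spec.autocorr_range)
              for _ in range(spec.n_layers)]
    if spec.n_layers >= 2:
        a, b = spec.correlated_pair
        rho = spec.correlated_pair_rho
        mixed = rho * fields[a] + np.sqrt(1.0 - rho ** 2) * fields[b]
        fields[b] = (mixed - mixed.mean()) / mixed.std()
    layers = {f"env_{i + 1}": f for i, f in enumerate(fields)}
    return EnvStack(layers, spec.transform, set_id="set_1")


def gibbs_suitability(stack: EnvStack, lambda_true: np.ndarray) -> np.ndarray:
    """Un-normalized Gibbs surface exp(lambda . layers) (nodata -> 0)."""
    lam = np.asarray(lambda_true, dtype=float)
    if lam.size != stack.n_layers:
        raise ValueError("lambda_true length must match layer count")
    eta = np.tensordot(lam, stack.array(), axes=(0, 0))
    eta = eta - np.nanmax(eta)
    suit = np.exp(eta)
    suit[stack.nodata_mask] = 0.0
    return suit


def sample_occurrences(stack: EnvStack, truth: TruthParams, n: int,
                       bias_strength: float = 0.0, seed: int = 0) -> OccurrenceSet:
    """Sample ``n`` occurrence records with cell probability proportional to
    the true Gibbs suitability times exp(bias_strength * smooth bias field);
    records take cell-centre coordinates and the source tag ``synthetic``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if bias_strength < 0:
        raise ValueError("bias_strength must be nonnegative")
    rng = np.random.default_rng(seed)
    suit = gibbs_suitability(stack, truth.lambda_true)
    if bias_strength > 0:
        bias = _smooth_field(rng, stack.shape, max(2.0, min(stack.shape) / 10.0))
        weights = suit * np.exp(bias_strength * bias)
    else:
        weights = suit.copy()
    weights[stack.nodata_mask] = 0.0
    total = weights.sum()
    if total <= 0:
        raise ValueError("all suitability mass sits on nodata cells")
    pvec = (weights / total).ravel()
    cells = rng.choice(pvec.size, size=n, replace=True, p=pvec)
    rows, cols = np.unravel_index(cells, stack.shape)
    lon, lat = stack.transform.cell_center(rows, cols)
    df = pd.DataFrame({"id": [f"syn_{i:05d}" for i in range(n)],
                       "lon": lon, "lat": lat, "source": "synthetic"})
    return OccurrenceSet(df)


def simulate_detection_histories(site_cov: pd.DataFrame,
                                 survey_cov: dict[str, np.ndarray] | None,
                                 truth: TruthParams, n_sites: int,
                                 n_occasions: int, seed: int = 0) -> DetectionData:
    """Simulate single-season detection histories with known truth.

    Latent occupancy z_i ~ Bernoulli(psi_i) with
    logit(psi_i) = [1 | site_cov] beta_psi_true; detections
    y_ij ~ Bernoulli(z_i * p_ij) with logit(p_ij) = [1 | survey_cov] alpha_p_true.
    A ``missing_fraction`` of survey cells is marked unconducted uniformly at
    random, never leaving a site with zero conducted surveys.
    """
    survey_cov = dict(survey_cov or {})
    if len(site_cov) != n_sites:
        raise ValueError("site covariate table must have n_sites rows")
    for name, arr in survey_cov.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (n_sites, n_occasions):
            raise ValueError(f"survey covariate {name!r} must be sites x occasions")
        survey_cov[name] = arr
    beta = truth.beta_psi_true
    alpha = truth.alpha_p_true
    if beta.size != 1 + site_cov.shape[1]:
        raise ValueError("beta_psi_true length must be 1 + number of site covariates")
    if alpha.size != 1 + len(survey_cov):
        raise ValueError("alpha_p_true length must be 1 + number of survey covariates")

    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n_sites)] + [site_cov[c].to_numpy(dtype=float)
                                              for c in site_cov.columns])
    psi = expit(X @ beta)
    Wl = np.zeros((n_sites, n_occasions)) + alpha[0]
    for k, (name, arr) in enumerate(survey_cov.items()):
        Wl += alpha[1 + k] * arr
    p = expit(Wl)
    z = rng.random(n_sites) < psi
    y = ((rng.random((n_sites, n_occasions)) < p) & z[:, None]).astype(float)

    n_cells = n_sites * n_occasions
    n_missing = int(round(truth.missing_fraction * n_cells))
    if n_missing > 0:
        for _ in range(1000):
            miss = rng.choice(n_cells, size=n_missing, replace=False)
            mask = np.zeros(n_cells, dtype=bool)
            mask[miss] = True
            mask = mask.reshape(n_sites, n_occasions)
            if not mask.all(axis=1).any():
                break
        else:
            raise RuntimeError("could not place missing surveys without "
                               "emptying a site")
        y[mask] = np.nan
    return DetectionData(y, site_cov.copy(), survey_cov)


def default_site_covariates(n_sites: int, seed: int = 0,
                            names: Sequence[str] = ("Veg_H", "Slope", "N_obj",
                                                    "Hori0", "Leaf_Dep")
                            ) -> pd.DataFrame:
    """Plausible site-covariate table for simulations: vegetation height (m),
    slope (deg), cover-object count, horizon-0 depth (cm), leaf-litter
    depth (cm)."""
    rng = np.random.default_rng(seed)
    gens = {
        "Veg_H": lambda: rng.gamma(2.0, 1.5, n_sites),        # metres, ~0.5-8
        "Slope": lambda: rng.gamma(2.0, 5.0, n_sites),        # degrees
        "N_obj": lambda: rng.poisson(9.0, n_sites).astype(float),
        "Hori0": lambda: rng.gamma(2.0, 2.0, n_sites),        # cm
        "Leaf_Dep": lambda: rng.gamma(1.5, 1.0, n_sites),     # cm
    }
    cols = {}
    for name in names:
        cols[name] = gens[name]() if name in gens else rng.normal(0, 1, n_sites)
    return pd.DataFrame(cols)


def default_survey_covariates(n_sites: int, n_occasions: int, seed: int = 0,
                              names: Sequence[str] = ("Soil_moisture", "T_ground")
                              ) -> dict[str, np.ndarray]:
    """Plausible survey-covariate arrays: soil moisture (%) and ground
    temperature (deg C) varying by site and visit."""
    rng = np.random.default_rng(seed)
    shape = (n_sites, n_occasions)
    gens = {
        "Soil_moisture": lambda: np.clip(rng.normal(35.0, 10.0, shape), 0, 100),
        "T_ground": lambda: rng.normal(18.0, 2.5, shape),
    }
    return {name: (gens[name]() if name in gens else rng.normal(0, 1, shape))
            for name in names}
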