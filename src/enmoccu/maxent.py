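"""Maximum-entropy niche model: features, penalized Gibbs likelihood, fit.

The model estimates a Gibbs distribution over background cells,

    P(x) = exp(lambda . f(x)) / Z,

by minimizing the L1-penalized log loss

    J(lambda) = -(1/m) sum_presences lambda.f(x)
                + log sum_background exp(lambda.f(x))
                + sum_j beta_j |lambda_j|,

a convex objective solved here by FISTA (accelerated proximal gradient with
backtracking).  Per-feature penalty weights follow the Phillips-Dudik
scheme: beta_j = reg_multiplier * beta_class(m) * sqrt(var_j / m), where
beta_class(m) interpolates the published default tables by presence count m
and var_j is the feature variance over the presence sample.

Feature classes are linear (l), quadratic (q) and their union (lq); layers
are min-max rescaled to [0, 1] over the background before squaring, and
projection values outside the background range clamp to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from .prep import OccurrenceSet
from .raster import EnvStack

FEATURE_COMBINATIONS = ("l", "q", "lq")

# Published default-beta interpolation tables (presence count -> beta),
# clamped at both ends.
_BETA_TABLES = {
    "linear": (np.array([10.0, 30.0, 100.0]), np.array([1.0, 0.2, 0.05])),
    "quadratic": (np.array([0.0, 10.0, 17.0, 30.0, 100.0]),
                  np.array([1.3, 0.8, 0.5, 0.25, 0.05])),
}


def default_beta(feature_class: str, m: int) -> float:
    """Interpolated default regularization weight for a feature class at
    presence count ``m`` (values clamp outside the tabulated range)."""
    xs, ys = _BETA_TABLES[feature_class]
    return float(np.interp(float(m), xs, ys))


@dataclass
class FeatureSpec:
    """Feature construction recipe: which classes, plus the background
    min/max per layer used for [0, 1] rescaling."""

    combination: str                      # 'l', 'q' or 'lq'
    layer_names: list[str]
    lower: np.ndarray                     # per-layer background minima
    upper: np.ndarray                     # per-layer background maxima

    def __post_init__(self):
        if self.combination not in FEATURE_COMBINATIONS:
            raise ValueError(f"unknown feature combination {self.combination!r}")
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (np.isfinite(self.lower).all() and np.isfinite(self.upper).all()):
            raise ValueError("feature scaling bounds must be finite")
        flat = np.isclose(self.upper, self.lower)
        if flat.any():
            bad = [self.layer_names[i] for i in np.flatnonzero(flat)]
            raise ValueError(f"constant layer(s) over background: {bad}")

    @classmethod
    def from_background(cls, values: np.ndarray, layer_names: Sequence[str],
                        combination: str) -> "FeatureSpec":
        values = np.asarray(values, dtype=float)
        return cls(combination=combination, layer_names=list(layer_names),
                   lower=values.min(axis=0), upper=values.max(axis=0))

    @property
    def classes(self) -> tuple[str, ...]:
        return {"l": ("linear",), "q": ("quadratic",),
                "lq": ("linear", "quadratic")}[self.combination]

    @property
    def feature_names(self) -> list[str]:
        names = []
        if "linear" in self.classes:
            names += list(self.layer_names)
        if "quadratic" in self.classes:
            names += [f"{n}^2" for n in self.layer_names]
        return names

    @property
    def feature_classes(self) -> list[str]:
        out = []
        if "linear" in self.classes:
            out += ["linear"] * len(self.layer_names)
        if "quadratic" in self.classes:
            out += ["quadratic"] * len(self.layer_names)
        return out

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Map raw layer values (n_cells, n_layers) to the feature matrix.

        Values outside the background range clamp to [0, 1] (projection rule).
        """
        values = np.asarray(values, dtype=float)
        scaled = (values - self.lower) / (self.upper - self.lower)
        scaled = np.clip(scaled, 0.0, 1.0)
        blocks = []
        if "linear" in self.classes:
            blocks.append(scaled)
        if "quadratic" in self.classes:
            blocks.append(scaled ** 2)
        return np.concatenate(blocks, axis=1)


def make_features(stack: EnvStack, spec: FeatureSpec,
                  cells: np.ndarray | None = None) -> np.ndarray:
    """Feature matrix for a stack (valid cells, or the given flat cell ids)."""
    if cells is None:
        values = stack.valid_values(spec.layer_names)
    else:
        flat = [stack.layers[n].ravel()[cells] for n in spec.layer_names]
        values = np.column_stack(flat)
    return spec.transform(values)


class ConvergenceError(RuntimeError):
    pass


class MaxentModel:
    """Penalized maximum-entropy model of presence cells against background.

    Parameters
    ----------
    presence_features, background_features
        Feature matrices (rows = cells) built by one :class:`FeatureSpec`.
        Presences may also be background cells; no disjointness is assumed.
    reg_multiplier
        Scalar multiplying every per-feature default penalty (study grid
        0.1-5; 1 is the conventional default).
    feature_classes
        Class label per feature column ('linear'/'quadratic'), used to look
        up the default betas.  Taken from ``feature_spec`` when given.
    """

    def __init__(self, presence_features: np.ndarray,
                 background_features: np.ndarray,
                 reg_multiplier: float = 1.0,
                 feature_spec: FeatureSpec | None = None,
                 feature_classes: Sequence[str] | None = None,
                 background_ids: np.ndarray | None = None,
                 set_id: str | None = None):
        self.F = np.asarray(presence_features, dtype=float)
        self.B = np.asarray(background_features, dtype=float)
        if self.F.ndim != 2 or self.B.ndim != 2 or self.F.shape[1] != self.B.shape[1]:
            raise ValueError("presence/background feature matrices are inconsistent")
        if self.F.shape[0] < 5:
            raise ValueError("need at least 5 presence records")
        if reg_multiplier <= 0:
            raise ValueError("reg_multiplier must be positive")
        self.reg_multiplier = float(reg_multiplier)
        self.feature_spec = feature_spec
        if feature_classes is None:
            if feature_spec is None:
                raise ValueError("provide feature_spec or feature_classes")
            feature_classes = feature_spec.feature_classes
        self.feature_classes = list(feature_classes)
        if len(self.feature_classes) != self.F.shape[1]:
            raise ValueError("one class label per feature column required")
        self.background_ids = background_ids
        self.set_id = set_id
        m = self.F.shape[0]
        var = self.F.var(axis=0)  # ddof=0: invariant under presence duplication
        base = np.array([default_beta(c, m) for c in self.feature_classes])
        self.penalty = self.reg_multiplier * base * np.sqrt(np.maximum(var, 1e-12) / m)

    # -- objective pieces ---------------------------------------------------

    def _smooth_value_grad(self, lam: np.ndarray):
        mean_pres = self.F.mean(axis=0)
        eta = self.B @ lam
        lz = logsumexp(eta)
        p = softmax(eta)
        value = -float(mean_pres @ lam) + float(lz)
        grad = -mean_pres + p @ self.B
        return value, grad

    def objective(self, lam: np.ndarray) -> float:
        v, _ = self._smooth_value_grad(lam)
        return v + float(self.penalty @ np.abs(lam))

    def _converged(self, lam: np.ndarray, tol: float) -> bool:
        _, g = self._smooth_value_grad(lam)
        nz = lam != 0.0
        kkt = np.where(nz, np.abs(g + self.penalty * np.sign(lam)),
                       np.maximum(np.abs(g) - self.penalty, 0.0))
        return bool(kkt.max() < tol)

    # -- fitting ------------------------------------------------------------

    def fit(self, max_iter: int = 20000, tol: float = 1e-6) -> "MaxentResults":
        """FISTA with backtracking on the convex penalized objective.

        Convergence: KKT residual (sup-norm of the smooth gradient shifted
        by the active L1 subgradient) below ``tol``.
        """
        k = self.F.shape[1]
        lam = np.zeros(k)
        z = lam.copy()
        t = 1.0
        step = 1.0
        f_z, g_z = self._smooth_value_grad(z)
        for it in range(max_iter):
            # backtracking proximal step from z
            while True:
                cand = np.sign(z - step * g_z) * np.maximum(
                    np.abs(z - step * g_z) - step * self.penalty, 0.0)
                d = cand - z
                f_cand, _ = self._smooth_value_grad(cand)
                if f_cand <= f_z + g_z @ d + (d @ d) / (2.0 * step) + 1e-12:
                    break
                step *= 0.5
                if step < 1e-14:
                    break
            t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
            z = cand + ((t - 1.0) / t_new) * (cand - lam)
            lam, t = cand, t_new
            if it % 10 == 0 and self._converged(lam, tol):
                break
            f_z, g_z = self._smooth_value_grad(z)
            step = min(step * 2.0, 1e6)
        else:
            if not self._converged(lam, tol):
                _, g = self._smooth_value_grad(lam)
                raise ConvergenceError(
                    f"maxent fit did not converge in {max_iter} iterations "
                    f"(KKT residual {np.abs(g).max():.3g}, reg={self.reg_multiplier})")
        return MaxentResults(self, lam)


class MaxentResults:
    """Fitted maximum-entropy model: weights, normalizer, entropy, predictions."""

    def __init__(self, model: MaxentModel, lam: np.ndarray):
        self.model = model
        self.lambda_ = np.asarray(lam, dtype=float)
        eta = model.B @ self.lambda_
        self.logZ = float(logsumexp(eta))
        p = softmax(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.entropy_H = float(-(p * np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)).sum())

    @property
    def n_params(self) -> int:
        """Count of nonzero feature weights (the K of information criteria)."""
        return int(np.count_nonzero(self.lambda_))

    def predict_raw(self, features: np.ndarray) -> np.ndarray:
        """Gibbs (raw) output: exp(lambda.f(x) - logZ); sums to 1 over the
        training background."""
        features = np.asarray(features, dtype=float)
        if features.shape[-1] != self.lambda_.shape[0]:
            raise ValueError("feature dimension mismatch")
        return np.exp(features @ self.lambda_ - self.logZ)

    def predict_cloglog(self, features: np.ndarray) -> np.ndarray:
        """Complementary log-log output in [0, 1]: 1 - exp(-e^H * raw)."""
        raw = self.predict_raw(features)
        return 1.0 - np.exp(-np.exp(self.entropy_H) * raw)

    def loglik(self, presence_features: np.ndarray) -> float:
        """Sum of log raw probabilities (background-normalized) at presences."""
        raw = self.predict_raw(presence_features)
        return float(np.sum(np.log(raw)))

    def summary(self) -> pd.DataFrame:
        names = (self.model.feature_spec.feature_names
                 if self.model.feature_spec is not None
                 else [f"f{i}" for i in range(len(self.lambda_))])
        return pd.DataFrame({
            "feature": names,
            "class": self.model.feature_classes,
            "lambda": self.lambda_,
            "penalty": self.model.penalty,
        })


# ---------------------------------------------------------------------------
# Candidate grid

@dataclass
class DataSplit:
    """Random train/test partition of occurrence indices (shared by all
    candidates so that evaluation is comparable)."""

    n: int
    fraction: float = 0.2
    seed: int = 0
    train_ids: np.ndarray = field(init=False)
    test_ids: np.ndarray = field(init=False)

    def __post_init__(self):
        if not (0.0 < self.fraction < 1.0):
            raise ValueError("test fraction must be in (0, 1)")
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(self.n)
        n_test = max(1, int(round(self.fraction * self.n)))
        self.test_ids = np.sort(perm[:n_test])
        self.train_ids = np.sort(perm[n_test:])


@dataclass
class Candidate:
    """One fitted candidate of the (regularization x features x set) grid."""

    model_id: str
    reg_multiplier: float
    feature_label: str
    set_id: str
    results: MaxentResults | None
    spec: FeatureSpec | None
    train_raw: np.ndarray | None = None       # raw suitability at training presences
    test_raw: np.ndarray | None = None
    background_raw: np.ndarray | None = None
    train_cloglog: np.ndarray | None = None
    test_cloglog: np.ndarray | None = None
    background_cloglog: np.ndarray | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.results is not None


def candidate_id(reg: float, feature_label: str, set_id: str) -> str:
    return f"M_{reg:g}_F_{feature_label}_{set_id}"


def presence_cells(occ: OccurrenceSet, stack: EnvStack) -> np.ndarray:
    """Flat cell index of the cell containing each record (cell-centre snap);
    records outside the grid or on nodata are dropped."""
    row, col = stack.transform.rowcol(occ.lons, occ.lats)
    ok = stack.transform.contains_rowcol(row, col)
    flat = row[ok] * stack.transform.n_cols + col[ok]
    valid = ~stack.nodata_mask.ravel()[flat]
    return flat[valid]


def background_cells(stack: EnvStack, max_background: int = 10_000,
                     seed: int = 0) -> np.ndarray:
    """All valid cells, or a seeded uniform sample when there are more than
    ``max_background`` of them."""
    flat = np.flatnonzero(~stack.nodata_mask.ravel())
    if flat.size > max_background:
        rng = np.random.default_rng(seed)
        flat = np.sort(rng.choice(flat, size=max_background, replace=False))
    return flat


def run_candidate_grid(occ: OccurrenceSet, sets: Sequence[EnvStack],
                       reg_values: Sequence[float],
                       feature_labels: Sequence[str],
                       split: DataSplit,
                       max_background: int = 10_000,
                       background_seed: int = 0) -> list[Candidate]:
    """Fit one candidate per (regularization, feature combination, variable
    set) triple, sharing one train/test split.  Individual fit failures are
    recorded on the candidate; only total failure raises.
    """
    if not (len(reg_values) and len(feature_labels) and len(sets)):
        raise ValueError("empty candidate grid")
    out: list[Candidate] = []
    for stack in sets:
        set_id = stack.set_id or "set_1"
        cells = presence_cells(occ, stack)
        if cells.size != len(occ):
            raise ValueError("some occurrences fall outside the variable-set grid")
        bg = background_cells(stack, max_background, background_seed)
        train_cells = cells[split.train_ids]
        test_cells = cells[split.test_ids]
        for label in feature_labels:
            flat_bg = np.column_stack([stack.layers[n].ravel()[bg] for n in stack.names])
            spec = FeatureSpec.from_background(flat_bg, stack.names, label)
            Fb = spec.transform(flat_bg)
            Ftr = make_features(stack, spec, train_cells)
            Fte = make_features(stack, spec, test_cells)
            for reg in reg_values:
                mid = candidate_id(reg, label, set_id)
                try:
                    res = MaxentModel(Ftr, Fb, reg_multiplier=reg, feature_spec=spec,
                                      background_ids=bg, set_id=set_id).fit()
                except Exception as exc:  # recorded, not fatal
                    out.append(Candidate(mid, reg, label, set_id, None, spec,
                                         error=str(exc)))
                    continue
                out.append(Candidate(
                    mid, reg, label, set_id, res, spec,
                    train_raw=res.predict_raw(Ftr),
                    test_raw=res.predict_raw(Fte),
                    background_raw=res.predict_raw(Fb),
                    train_cloglog=res.predict_cloglog(Ftr),
                    test_cloglog=res.predict_cloglog(Fte),
                    background_cloglog=res.predict_cloglog(Fb),
                ))
    if not any(c.ok for c in out):
        raise ConvergenceError("every candidate fit failed")
    return out
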