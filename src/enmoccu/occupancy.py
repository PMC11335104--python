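"""Single-season (closed) occupancy modelling with imperfect detection.

The model: each site i is occupied with probability psi_i, and, if occupied,
detected on conducted survey j with probability p_ij, with logit-linear
covariate effects on both scales:

    logit(psi_i) = x_i' beta,      logit(p_ij) = w_ij' alpha.

The site likelihood marginalizes the latent occupancy state:

    L_i = psi_i * prod_j p_ij^y_ij (1 - p_ij)^(1 - y_ij)
          + (1 - psi_i) * 1{no detection at site i},

with the product over *conducted* surveys only (missing occasions contribute
nothing).  Maximum-likelihood fitting uses quasi-Newton optimization with
seeded jittered restarts; AICc uses the number of sites as the sample size.

Also here: detection-first two-stage model selection, the MacKenzie-Bailey
parametric-bootstrap chi-square goodness-of-fit test, prediction curves with
delta-method confidence intervals, and naive occupancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from statsmodels.tools.numdiff import approx_hess2

_P_EPS = 1e-12


@dataclass
class DetectionData:
    """Sites x occasions detection histories plus covariates.

    ``y`` holds 0/1 with NaN marking surveys not conducted.  Site covariates
    are one row per site; survey covariates are one (sites x occasions)
    array per name.  ``standardization`` records per-covariate (mean, sd)
    when covariates have been standardized (the modelling default).
    """

    y: np.ndarray
    site_covariates: pd.DataFrame
    survey_covariates: dict[str, np.ndarray] = field(default_factory=dict)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be sites x occasions")
        vals = self.y[~np.isnan(self.y)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("non-missing detections must be 0 or 1")
        if np.isnan(self.y).all(axis=1).any():
            raise ValueError("every site needs at least one conducted survey")
        if len(self.site_covariates) != self.n_sites:
            raise ValueError("site covariate table has wrong number of rows")
        for name, arr in self.survey_covariates.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.y.shape:
                raise ValueError(f"survey covariate {name!r} shape mismatch")
            self.survey_covariates[name] = arr

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    @property
    def conducted(self) -> np.ndarray:
        return ~np.isnan(self.y)

    @property
    def n_surveys(self) -> int:
        return int(self.conducted.sum())

    def covariate_names(self) -> list[str]:
        return list(self.site_covariates.columns) + list(self.survey_covariates)

    def standardize(self) -> "DetectionData":
        """Return a copy with every covariate centred and scaled to unit sd
        (survey covariates standardized over conducted surveys), recording
        the (mean, sd) pairs for later destandardization."""
        record: dict[str, tuple[float, float]] = {}
        site = self.site_covariates.copy()
        for name in site.columns:
            mu = float(site[name].mean())
            sd = float(site[name].std(ddof=0))
            if sd == 0:
                raise ValueError(f"site covariate {name!r} is constant")
            site[name] = (site[name] - mu) / sd
            record[name] = (mu, sd)
        survey: dict[str, np.ndarray] = {}
        for name, arr in self.survey_covariates.items():
            ok = self.conducted & np.isfinite(arr)
            mu = float(arr[ok].mean())
            sd = float(arr[ok].std())
            if sd == 0:
                raise ValueError(f"survey covariate {name!r} is constant")
            survey[name] = (arr - mu) / sd
            record[name] = (mu, sd)
        return DetectionData(self.y.copy(), site, survey, record)

    def destandardize(self, name: str, z):
        mu, sd = self.standardization[name]
        return np.asarray(z) * sd + mu

    def standardize_value(self, name: str, x):
        mu, sd = self.standardization[name]
        return (np.asarray(x) - mu) / sd

    # -- text I/O -----------------------------------------------------------

    def to_csv(self, directory: str | Path, prefix: str = "detection") -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        ydf = pd.DataFrame(self.y, columns=[f"occasion_{j + 1}"
                                            for j in range(self.n_occasions)])
        p = directory / f"{prefix}_histories.csv"
        ydf.to_csv(p, index=False, na_rep="NA")
        paths["histories"] = p
        p = directory / f"{prefix}_site_covariates.csv"
        self.site_covariates.to_csv(p, index=False, na_rep="NA")
        paths["site_covariates"] = p
        for name, arr in self.survey_covariates.items():
            p = directory / f"{prefix}_survey_{name}.csv"
            pd.DataFrame(arr, columns=ydf.columns).to_csv(p, index=False, na_rep="NA")
            paths[f"survey_{name}"] = p
        return paths

    @classmethod
    def from_csv(cls, histories: str | Path, site_covariates: str | Path,
                 survey_covariates: Mapping[str, str | Path] | None = None
                 ) -> "DetectionData":
        y = pd.read_csv(histories, na_values=["NA"]).to_numpy(dtype=float)
        site = pd.read_csv(site_covariates, na_values=["NA"])
        survey = {name: pd.read_csv(p, na_values=["NA"]).to_numpy(dtype=float)
                  for name, p in (survey_covariates or {}).items()}
        return cls(y, site, survey)


def naive_occupancy(data: DetectionData) -> float:
    """Fraction of sites with at least one detection among conducted surveys."""
    det = np.nansum(data.y, axis=1) > 0
    return float(det.mean())


# ---------------------------------------------------------------------------
# Likelihood

def _design_matrices(data: DetectionData, psi_covariates: Sequence[str],
                     p_covariates: Sequence[str]):
    n, J = data.y.shape
    X = np.ones((n, 1 + len(psi_covariates)))
    for k, name in enumerate(psi_covariates):
        if name not in data.site_covariates.columns:
            raise KeyError(f"occupancy covariate {name!r} not in site covariates")
        X[:, 1 + k] = data.site_covariates[name].to_numpy(dtype=float)
    W = np.ones((n, J, 1 + len(p_covariates)))
    for k, name in enumerate(p_covariates):
        if name in data.survey_covariates:
            W[:, :, 1 + k] = data.survey_covariates[name]
        elif name in data.site_covariates.columns:
            W[:, :, 1 + k] = data.site_covariates[name].to_numpy(dtype=float)[:, None]
        else:
            raise KeyError(f"detection covariate {name!r} not found")
    # covariate values at unconducted surveys are irrelevant; zero them so
    # NaNs cannot poison the linear predictor
    W = np.where(data.conducted[:, :, None], W, 0.0)
    if not np.isfinite(X).all() or not np.isfinite(W).all():
        raise ValueError("non-finite covariate values in the design matrices")
    return X, W


def occupancy_loglik(data: DetectionData, beta_psi: np.ndarray, alpha_p: np.ndarray,
                     psi_covariates: Sequence[str] = (),
                     p_covariates: Sequence[str] = ()) -> float:
    """Log-likelihood of a single-season occupancy model at given
    coefficients (intercept-first, standardized covariate scale)."""
    X, W = _design_matrices(data, psi_covariates, p_covariates)
    return _loglik_core(data.y, data.conducted, X, W,
                        np.asarray(beta_psi, float), np.asarray(alpha_p, float))


def _loglik_core(y, conducted, X, W, beta, alpha) -> float:
    psi = expit(X @ beta)
    p = expit(W @ alpha)
    p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
    yy = np.where(conducted, y, 0.0)
    # per-site conditional log-likelihood of the history given occupancy
    term = yy * np.log(p) + (1.0 - yy) * np.log1p(-p)
    cond = np.where(conducted, term, 0.0).sum(axis=1)
    never = np.nansum(yy, axis=1) == 0
    lik = psi * np.exp(cond) + (1.0 - psi) * never
    return float(np.sum(np.log(np.maximum(lik, 1e-300))))


class OccupancyModel:
    """Single-season occupancy model specified by covariate name lists.

    Parameters
    ----------
    data
        Detection histories and covariates.  With ``standardize=True``
        (default) covariates are centred/scaled before fitting and the
        standardization record is carried on the fitted results.
    psi_covariates, p_covariates
        Names of occupancy- and detection-scale covariates (site covariates
        may appear on either scale; survey covariates on the detection
        scale only).
    """

    def __init__(self, data: DetectionData, psi_covariates: Sequence[str] = (),
                 p_covariates: Sequence[str] = (), standardize: bool = True):
        if standardize and not data.standardization and data.covariate_names():
            data = data.standardize()
        self.data = data
        self.psi_covariates = tuple(psi_covariates)
        self.p_covariates = tuple(p_covariates)
        if not (data.conducted.sum(axis=1) >= 2).any():
            raise ValueError("identifiability requires >= 2 occasions at some sites")
        self.X, self.W = _design_matrices(data, self.psi_covariates, self.p_covariates)
        self.k_psi = self.X.shape[1]
        self.k_p = self.W.shape[2]

    @classmethod
    def from_dataframes(cls, histories: pd.DataFrame, site_covariates: pd.DataFrame,
                        survey_covariates: Mapping[str, np.ndarray] | None = None,
                        psi_covariates: Sequence[str] = (),
                        p_covariates: Sequence[str] = (), **kw) -> "OccupancyModel":
        data = DetectionData(histories.to_numpy(dtype=float), site_covariates,
                             dict(survey_covariates or {}))
        return cls(data, psi_covariates, p_covariates, **kw)

    @property
    def label(self) -> str:
        p = "+".join(self.p_covariates) or "."
        psi = "+".join(self.psi_covariates) or "."
        return f"p({p}) psi({psi})"

    def _split(self, params: np.ndarray):
        return params[:self.k_psi], params[self.k_psi:]

    def loglike(self, params: np.ndarray) -> float:
        beta, alpha = self._split(np.asarray(params, dtype=float))
        return _loglik_core(self.data.y, self.data.conducted, self.X, self.W,
                            beta, alpha)

    def fit(self, start: np.ndarray | None = None, n_restarts: int = 5,
            seed: int = 0, maxiter: int = 500) -> "OccupancyResults":
        """Maximize the likelihood by BFGS from zero-initialized coefficients
        plus seeded N(0, 0.5) jittered restarts; the best optimum wins."""
        k = self.k_psi + self.k_p
        rng = np.random.default_rng(seed)
        starts = [np.zeros(k) if start is None else np.asarray(start, dtype=float)]
        starts += [starts[0] + rng.normal(0.0, 0.5, size=k)
                   for _ in range(max(0, n_restarts - 1))]
        nll = lambda th: -self.loglike(th)
        best = None
        for s in starts:
            res = minimize(nll, s, method="BFGS",
                           options={"maxiter": maxiter, "gtol": 1e-6})
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        params = best.x
        llf = -best.fun
        converged = bool(best.success or np.linalg.norm(best.jac, np.inf) < 1e-3)
        flagged_reason = None
        if np.nansum(self.data.y) == 0:
            flagged_reason = "no detections anywhere: psi and p are not separately identifiable"
        elif np.abs(params).max() > 15.0:
            flagged_reason = "estimates on the logit boundary (possible complete separation)"
        elif not converged:
            flagged_reason = f"optimizer did not converge: {best.message}"
        return OccupancyResults(self, params, llf, converged and flagged_reason is None,
                                flagged_reason)


class OccupancyResults:
    """MLE results: coefficients, covariance, AICc, prediction, simulation."""

    def __init__(self, model: OccupancyModel, params: np.ndarray, llf: float,
                 converged: bool, flagged_reason: str | None = None):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.llf = float(llf)
        self.converged = converged
        self.flagged_reason = flagged_reason
        self._cov = None

    @property
    def beta_psi(self) -> np.ndarray:
        return self.params[:self.model.k_psi]

    @property
    def alpha_p(self) -> np.ndarray:
        return self.params[self.model.k_psi:]

    @property
    def K(self) -> int:
        return self.params.size

    @property
    def aicc(self) -> float:
        """AICc with n = number of sites."""
        n = self.model.data.n_sites
        k = self.K
        if n <= k + 1:
            return float("nan")
        return -2.0 * self.llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def label(self) -> str:
        return self.model.label

    def cov_params(self) -> np.ndarray:
        """Covariance from the inverse observed information (numerical
        Hessian of the negative log-likelihood at the MLE)."""
        if self._cov is None:
            H = approx_hess2(self.params, lambda th: -self.model.loglike(th))
            try:
                self._cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                warnings.warn("singular information matrix; covariance unavailable")
                self._cov = np.full((self.K, self.K), np.nan)
        return self._cov

    def bse(self) -> np.ndarray:
        var = np.diag(self.cov_params())
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.where(var > 0, var, np.nan))

    # -- prediction ---------------------------------------------------------

    def predict_psi(self, site_values: Mapping[str, np.ndarray] | pd.DataFrame | None = None
                    ) -> np.ndarray:
        """Occupancy probability; with no argument, at the fitted sites.
        Supplied values are on the *natural* scale and are standardized via
        the recorded (mean, sd) pairs."""
        if site_values is None:
            return expit(self.model.X @ self.beta_psi)
        if isinstance(site_values, pd.DataFrame):
            site_values = {c: site_values[c].to_numpy(dtype=float)
                           for c in site_values.columns}
        names = self.model.psi_covariates
        n = len(next(iter(site_values.values()))) if site_values else 1
        X = np.ones((n, 1 + len(names)))
        for k, name in enumerate(names):
            v = np.asarray(site_values[name], dtype=float)
            if name in self.model.data.standardization:
                v = self.model.data.standardize_value(name, v)
            X[:, 1 + k] = v
        return expit(X @ self.beta_psi)

    def predict_curve(self, covariate: str, grid: np.ndarray,
                      scale_covariate: str | None = None,
                      conf_level: float = 0.95) -> pd.DataFrame:
        """Occupancy (or detection) response curve over a natural-unit grid
        of one covariate, others held at their standardized mean (0), with
        delta-method confidence intervals on the logit scale."""
        from scipy.stats import norm
        grid = np.asarray(grid, dtype=float)
        on_psi = covariate in self.model.psi_covariates
        on_p = covariate in self.model.p_covariates
        if not (on_psi or on_p):
            raise KeyError(f"covariate {covariate!r} is not in the fitted model")
        z = (self.model.data.standardize_value(covariate, grid)
             if covariate in self.model.data.standardization else grid)
        if on_psi:
            names, offset = self.model.psi_covariates, 0
        else:
            names, offset = self.model.p_covariates, self.model.k_psi
        idx = names.index(covariate)
        G = np.zeros((grid.size, self.K))
        G[:, offset] = 1.0
        G[:, offset + 1 + idx] = z
        eta = G @ self.params
        cov = self.cov_params()
        var = np.einsum("ij,jk,ik->i", G, cov, G)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.maximum(var, 0.0))
        q = norm.ppf(0.5 + conf_level / 2.0)
        return pd.DataFrame({
            covariate: grid,
            "estimate": expit(eta),
            "lower": expit(eta - q * se),
            "upper": expit(eta + q * se),
        })

    def plot_curve(self, covariate: str, grid: np.ndarray, ax=None):
        """Prediction-curve plot (matplotlib)."""
        import matplotlib.pyplot as plt
        curve = self.predict_curve(covariate, grid)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve[covariate], curve["estimate"], color="k")
        ax.fill_between(curve[covariate], curve["lower"], curve["upper"],
                        alpha=0.3, color="grey")
        ax.set_xlabel(covariate)
        ax.set_ylabel("occupancy" if covariate in self.model.psi_covariates
                      else "detection probability")
        return ax

    # -- simulation ---------------------------------------------------------

    def simulate(self, seed: int = 0) -> DetectionData:
        """Parametric simulation from the fitted model, preserving the
        observed missingness pattern and all covariates."""
        rng = np.random.default_rng(seed)
        data = self.model.data
        psi = expit(self.model.X @ self.beta_psi)
        p = expit(self.model.W @ self.alpha_p)
        z = rng.random(data.n_sites) < psi
        y = (rng.random(data.y.shape) < p) & z[:, None]
        y = np.where(data.conducted, y.astype(float), np.nan)
        return DetectionData(y, data.site_covariates.copy(),
                             {k: v.copy() for k, v in data.survey_covariates.items()},
                             dict(data.standardization))

    def summary(self) -> str:
        se = self.bse()
        lines = [f"Single-season occupancy model  {self.label}",
                 f"  sites: {self.model.data.n_sites}   occasions: {self.model.data.n_occasions}"
                 f"   conducted surveys: {self.model.data.n_surveys}",
                 f"  logLik = {self.llf:.3f}   K = {self.K}   AICc = {self.aicc:.3f}",
                 f"  converged: {self.converged}"
                 + (f"   [{self.flagged_reason}]" if self.flagged_reason else ""),
                 "", "  Occupancy (logit scale):"]
        names_psi = ("(Intercept)",) + self.model.psi_covariates
        for name, est, s in zip(names_psi, self.beta_psi, se[:self.model.k_psi]):
            lines.append(f"    {name:<14s} {est: .4f}  (SE {s:.4f})")
        lines.append("  Detection (logit scale):")
        names_p = ("(Intercept)",) + self.model.p_covariates
        for name, est, s in zip(names_p, self.alpha_p, se[self.model.k_psi:]):
            lines.append(f"    {name:<14s} {est: .4f}  (SE {s:.4f})")
        return "\n".join(lines)


def fit_occupancy(data: DetectionData, p_covariates: Sequence[str] = (),
                  psi_covariates: Sequence[str] = (), **fit_kw) -> OccupancyResults:
    """Convenience wrapper: build and fit in one call."""
    return OccupancyModel(data, psi_covariates=psi_covariates,
                          p_covariates=p_covariates).fit(**fit_kw)


# ---------------------------------------------------------------------------
# Model tables and two-stage selection

def build_model_table(fits: Sequence[OccupancyResults]) -> pd.DataFrame:
    """AICc comparison table (Model, K, AICc, Delta_AICc, AICcWt, Cum.Wt)
    over converged fits, sorted ascending by AICc."""
    from .evaluation import akaike_table
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to tabulate")
    return akaike_table([f.label for f in ok], [f.aicc for f in ok],
                        [f.K for f in ok])


def two_stage_selection(data: DetectionData,
                        detection_candidates: Sequence[Sequence[str]],
                        occupancy_candidates: Sequence[Sequence[str]],
                        n_restarts: int = 5, seed: int = 0
                        ) -> tuple[OccupancyResults, pd.DataFrame, list[OccupancyResults]]:
    """Detection-first selection: stage 1 fits p(candidate) psi(.) models and
    keeps the AICc-best detection structure; stage 2 fits psi candidates with
    that detection structure.  Returns (best stage-2 fit, stage-2 table,
    stage-2 fits)."""
    if not detection_candidates or not occupancy_candidates:
        raise ValueError("candidate lists must be non-empty")
    for cand in list(detection_candidates) + list(occupancy_candidates):
        if len(cand) > 2:
            raise ValueError(f"candidate {cand} has more than two covariates")
    if not data.standardization and data.covariate_names():
        data = data.standardize()
    stage1 = []
    for cand in detection_candidates:
        try:
            fit = OccupancyModel(data, psi_covariates=(), p_covariates=cand,
                                 standardize=False).fit(n_restarts=n_restarts, seed=seed)
        except Exception:
            continue
        if fit.converged:
            stage1.append(fit)
    if not stage1:
        raise ValueError("all detection-stage fits failed")
    best_p = min(stage1, key=lambda f: f.aicc).model.p_covariates
    stage2 = []
    for cand in occupancy_candidates:
        try:
            fit = OccupancyModel(data, psi_covariates=cand, p_covariates=best_p,
                                 standardize=False).fit(n_restarts=n_restarts, seed=seed)
        except Exception:
            continue
        if fit.converged:
            stage2.append(fit)
    if not stage2:
        raise ValueError("all occupancy-stage fits failed")
    table = build_model_table(stage2)
    best = min(stage2, key=lambda f: f.aicc)
    return best, table, stage2


# ---------------------------------------------------------------------------
# Goodness of fit (MacKenzie-Bailey chi-square, parametric bootstrap)

def mb_chi2(results: OccupancyResults, data: DetectionData | None = None) -> float:
    """MacKenzie-Bailey chi-square on detection-history frequencies.

    Sites are grouped into cohorts sharing a missingness pattern; within a
    cohort the statistic sums (O_h - E_h)^2 / E_h over *observed* histories
    h, plus a pooled term for all unobserved histories (O = 0, E = cohort
    size minus the expected mass on observed histories)."""
    model = results.model
    data = data if data is not None else model.data
    X, W = _design_matrices(data, model.psi_covariates, model.p_covariates)
    psi = expit(X @ results.beta_psi)
    p = np.clip(expit(W @ results.alpha_p), _P_EPS, 1.0 - _P_EPS)
    conducted = data.conducted
    T = 0.0
    patterns: dict[tuple, list[int]] = {}
    for i in range(data.n_sites):
        patterns.setdefault(tuple(conducted[i]), []).append(i)
    for pattern, sites in patterns.items():
        occ_idx = [j for j, c in enumerate(pattern) if c]
        # observed history counts in this cohort
        hist_count: dict[tuple, int] = {}
        for i in sites:
            h = tuple(int(data.y[i, j]) for j in occ_idx)
            hist_count[h] = hist_count.get(h, 0) + 1
        exp_mass = 0.0
        for h, o in hist_count.items():
            harr = np.array(h, dtype=float)
            e = 0.0
            for i in sites:
                pij = p[i, occ_idx]
                cond = float(np.prod(np.where(harr == 1.0, pij, 1.0 - pij)))
                e += psi[i] * cond + (1.0 - psi[i]) * (harr.sum() == 0)
            exp_mass += e
            T += (o - e) ** 2 / e
        # pooled unobserved-histories term: O = 0, E = remaining mass
        e_rest = len(sites) - exp_mass
        if e_rest > 1e-12:
            T += e_rest
    return float(T)


def parametric_bootstrap_gof(results: OccupancyResults, n_sim: int = 1000,
                             seed: int = 0, n_restarts: int = 1
                             ) -> tuple[float, float, np.ndarray]:
    """Parametric-bootstrap goodness-of-fit test on a fitted model.

    Simulates ``n_sim`` datasets from the fit (preserving the missingness
    pattern), refits each, and compares the MacKenzie-Bailey chi-square of
    the refit against the observed statistic.  Returns
    (T_obs, p, simulated T values) with p = (1 + #{T_s >= T_obs}) / (n_ok + 1).
    Refit failures are dropped with a warning if they stay under 10%.
    """
    if not results.converged:
        raise ValueError("goodness of fit requires a converged fit")
    t_obs = mb_chi2(results)
    rng = np.random.default_rng(seed)
    sims = []
    failures = 0
    for s in range(n_sim):
        sim_data = results.simulate(seed=int(rng.integers(0, 2 ** 31 - 1)))
        try:
            refit = OccupancyModel(sim_data, psi_covariates=results.model.psi_covariates,
                                   p_covariates=results.model.p_covariates,
                                   standardize=False
                                   ).fit(start=results.params, n_restarts=n_restarts)
            sims.append(mb_chi2(refit))
        except Exception:
            failures += 1
    if failures:
        if failures > 0.1 * n_sim:
            raise RuntimeError(f"{failures}/{n_sim} bootstrap refits failed")
        warnings.warn(f"{failures}/{n_sim} bootstrap refits failed and were dropped")
    sims = np.asarray(sims)
    p = (1.0 + float(np.sum(sims >= t_obs))) / (sims.size + 1.0)
    return t_obs, p, sims
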