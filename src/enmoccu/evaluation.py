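"""Candidate evaluation and selection for the niche model.

Implements the study's joint evaluation criteria — omission rate at the E%
training threshold, bootstrap partial ROC (AUC ratio against the random
expectation over the high-sensitivity region), and AICc on the raw Gibbs
output (Warren-Seifert convention: likelihood renormalized over all
background cells, K = count of nonzero weights) — plus the Akaike
delta/weight machinery shared with the occupancy module, the cell-wise
median consensus, and threshold-based binarization using the mean
10th-percentile training-presence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .maxent import Candidate, MaxentResults
from .raster import GridTransform


# ---------------------------------------------------------------------------
# Akaike machinery (shared by ENM and occupancy tables)

def akaike_deltas_weights(aicc: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Delta AICc and Akaike weights exp(-delta/2)/sum over a candidate set."""
    aicc = np.asarray(aicc, dtype=float)
    delta = aicc - np.nanmin(aicc)
    rel = np.exp(-delta / 2.0)
    rel = np.where(np.isfinite(rel), rel, 0.0)
    return delta, rel / rel.sum()


def akaike_table(labels: Sequence[str], aicc: Sequence[float],
                 k: Sequence[int] | None = None) -> pd.DataFrame:
    """Model-comparison table sorted ascending by AICc with Delta AICc,
    AICc weights and cumulative weights (ties broken by label for
    stability)."""
    delta, weight = akaike_deltas_weights(aicc)
    df = pd.DataFrame({"Model": list(labels), "AICc": np.asarray(aicc, dtype=float),
                       "Delta_AICc": delta, "AICcWt": weight})
    if k is not None:
        df.insert(1, "K", list(k))
    df = df.sort_values(["AICc", "Model"], kind="mergesort").reset_index(drop=True)
    df["Cum.Wt"] = df["AICcWt"].cumsum()
    return df


# ---------------------------------------------------------------------------
# Per-candidate metrics

def omission_rate(test_suitability: np.ndarray, train_suitability: np.ndarray,
                  e_percent: float = 5.0) -> float:
    """Percent of test presences below the E% training-presence threshold.

    The threshold is the suitability value below which E% of *training*
    presences fall (linear-interpolation percentile).
    """
    train = np.asarray(train_suitability, dtype=float)
    test = np.asarray(test_suitability, dtype=float)
    if train.size == 0:
        raise ValueError("empty training suitability set")
    if test.size == 0:
        raise ValueError("empty test suitability set")
    tau = np.percentile(train, e_percent)
    return 100.0 * float(np.mean(test < tau))


def partial_roc(test_suitability: np.ndarray, background_suitability: np.ndarray,
                e_percent: float = 5.0, n_boot: int = 500,
                boot_fraction: float = 0.5, seed: int = 0
                ) -> tuple[float, float]:
    """Bootstrap partial-ROC AUC ratio (Peterson et al. style).

    The ROC here plots sensitivity (fraction of test presences at or above a
    threshold) against the fraction of the background predicted present, at
    thresholds spanning the background suitability distribution.  Both areas
    are integrated only over the region with sensitivity >= 1 - E/100; the
    ratio divides the model's partial area by that of the random-prediction
    diagonal.  Resampling draws ``boot_fraction`` of the test presences with
    replacement.  Returns (mean AUC ratio, p) with p the proportion of
    bootstrap ratios <= 1.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    test = np.asarray(test_suitability, dtype=float)
    bg = np.asarray(background_suitability, dtype=float)
    if np.ptp(bg) == 0:
        raise ValueError("constant suitability: partial ROC undefined")
    # threshold sweep over the background distribution (descending)
    thresholds = np.unique(np.quantile(bg, np.linspace(0.0, 1.0, 101)))[::-1]
    frac_area = np.array([np.mean(bg >= t) for t in thresholds])

    rng = np.random.default_rng(seed)
    n_take = max(1, int(round(boot_fraction * test.size)))
    sens_min = 1.0 - e_percent / 100.0
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        sample = test[rng.integers(0, test.size, size=n_take)]
        sens = np.array([np.mean(sample >= t) for t in thresholds])
        # the curve (x, sens) is monotone non-decreasing in both coordinates;
        # restrict to sens >= 1 - E by interpolating the single crossing
        if sens[-1] < sens_min:
            ratios[b] = np.nan
            continue
        if sens[0] >= sens_min:
            x0 = frac_area[0]
            xs = frac_area
            ys = sens
        else:
            i = int(np.searchsorted(sens, sens_min, side="left"))
            lo, hi = i - 1, i
            if sens[hi] == sens[lo]:
                x0 = frac_area[hi]
            else:
                x0 = frac_area[lo] + (sens_min - sens[lo]) * \
                    (frac_area[hi] - frac_area[lo]) / (sens[hi] - sens[lo])
            xs = np.concatenate([[x0], frac_area[hi:]])
            ys = np.concatenate([[sens_min], sens[hi:]])
        auc_model = np.trapezoid(ys, xs)
        auc_null = (xs[-1] ** 2 - x0 ** 2) / 2.0
        ratios[b] = auc_model / auc_null if auc_null > 0 else np.nan
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        raise ValueError("partial ROC could not be computed on any bootstrap sample")
    mean_ratio = float(ratios.mean())
    p_value = float(np.mean(ratios <= 1.0))
    return mean_ratio, p_value


def maxent_aicc(results: MaxentResults, presence_features: np.ndarray,
                background_features: np.ndarray | None = None
                ) -> tuple[float, int]:
    """AICc of a fitted maximum-entropy model at its presences.

    The likelihood uses raw output renormalized to sum to one over all
    background cells; K counts nonzero weights.  Returns (nan, K) when the
    small-sample correction is undefined (n <= K + 1).
    """
    raw_p = results.predict_raw(np.asarray(presence_features, dtype=float))
    if background_features is not None:
        total = float(results.predict_raw(background_features).sum())
    else:
        total = 1.0
    n = raw_p.shape[0]
    k = results.n_params
    ll = float(np.sum(np.log(raw_p / total)))
    if n <= k + 1:
        return float("nan"), k
    aicc = 2.0 * k - 2.0 * ll + 2.0 * k * (k + 1) / (n - k - 1)
    return aicc, k


@dataclass
class CandidateMetrics:
    model_id: str
    mean_auc_ratio: float
    pval_proc: float
    omission_rate_pct: float
    aicc: float
    num_parameters: int
    delta_aicc: float = float("nan")
    aicc_weight: float = float("nan")


def evaluate_candidates(candidates: Sequence[Candidate], e_percent: float = 5.0,
                        n_boot: int = 500, boot_fraction: float = 0.5,
                        seed: int = 0) -> pd.DataFrame:
    """Score every successful candidate; returns a table in the study's
    Table-1 layout (deltas/weights computed over all scored candidates)."""
    rows = []
    for c in candidates:
        if not c.ok:
            continue
        om = omission_rate(c.test_cloglog, c.train_cloglog, e_percent)
        try:
            ratio, pval = partial_roc(c.test_cloglog, c.background_cloglog,
                                      e_percent, n_boot, boot_fraction, seed)
        except ValueError:
            ratio, pval = float("nan"), 1.0
        # background_raw already spans the full background sample
        n = c.train_raw.shape[0]
        k = c.results.n_params
        ll = float(np.sum(np.log(c.train_raw / c.background_raw.sum())))
        aicc = (2.0 * k - 2.0 * ll + 2.0 * k * (k + 1) / (n - k - 1)
                if n > k + 1 else float("nan"))
        rows.append({"Model": c.model_id, "Mean AUC ratio": ratio,
                     "Pval pROC": pval, "Omission rate (%)": om,
                     "AICc": aicc, "Num parameters": k})
    if not rows:
        raise ValueError("no successful candidates to evaluate")
    df = pd.DataFrame(rows)
    delta, weight = akaike_deltas_weights(df["AICc"])
    df["Delta AICc"] = delta
    df["W AICc"] = weight
    return df


def select_models(metrics: pd.DataFrame, omission_max_pct: float = 5.0,
                  require_auc_ratio_gt: float = 1.0, pval_max: float = 0.05,
                  delta_aicc_max: float = 2.0) -> list[str]:
    """Apply the joint selection criteria: omission below the cap, mean AUC
    ratio above 1 with significant partial ROC, then Delta AICc <= 2
    *within the surviving set*.  Returns selected model ids (possibly
    empty)."""
    df = metrics.copy()
    ok = (
        (df["Omission rate (%)"] < omission_max_pct)
        & (df["Mean AUC ratio"] > require_auc_ratio_gt)
        & (df["Pval pROC"] < pval_max)
        & np.isfinite(df["AICc"])
    )
    df = df[ok]
    if df.empty:
        return []
    delta, _ = akaike_deltas_weights(df["AICc"])
    return list(df.loc[np.asarray(delta) <= delta_aicc_max, "Model"])


# ---------------------------------------------------------------------------
# Consensus and binarization

def consensus_median(grids: Sequence[np.ndarray]) -> np.ndarray:
    """Cell-wise median of aligned suitability grids; a cell is nodata (NaN)
    if it is nodata in any input."""
    if len(grids) == 0:
        raise ValueError("need at least one grid")
    arrs = [np.asarray(g, dtype=float) for g in grids]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("grids are not aligned")
    stacked = np.stack(arrs)
    out = np.median(stacked, axis=0)
    out[np.isnan(stacked).any(axis=0)] = np.nan
    return out


def training_presence_threshold(train_suitability: np.ndarray,
                                percentile: float = 10.0) -> float:
    """The E-percentile training-presence threshold of one model
    (linear-interpolation percentile)."""
    train = np.asarray(train_suitability, dtype=float)
    if train.size == 0:
        raise ValueError("empty training suitability set")
    return float(np.percentile(train, percentile))


def consensus_threshold(train_suitabilities: Sequence[np.ndarray],
                        percentile: float = 10.0) -> float:
    """Mean over selected models of each model's percentile training
    threshold — the cutoff applied to the consensus map."""
    return float(np.mean([training_presence_threshold(t, percentile)
                          for t in train_suitabilities]))


@dataclass
class BinaryMap:
    """A presence/absence grid: 1/0 with NaN for nodata, plus provenance."""

    grid: np.ndarray
    threshold: float
    transform: GridTransform | None = None
    provenance: tuple[str, ...] = ()

    @property
    def n_presence(self) -> int:
        return int(np.nansum(self.grid == 1))


def binarize(grid: np.ndarray, threshold: float,
             transform: GridTransform | None = None,
             provenance: Sequence[str] = ()) -> BinaryMap:
    """Threshold a suitability grid: cell = 1 iff suitability >= threshold
    (ties go to presence); nodata propagates."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    grid = np.asarray(grid, dtype=float)
    out = np.where(np.isnan(grid), np.nan, (grid >= threshold).astype(float))
    return BinaryMap(out, float(threshold), transform, tuple(provenance))
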