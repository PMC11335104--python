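import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from enmoccu.occupancy import (DetectionData, OccupancyModel, build_model_table,
                               fit_occupancy, mb_chi2, naive_occupancy,
                               occupancy_loglik, parametric_bootstrap_gof,
                               two_stage_selection)
from enmoccu.synthetic import TruthParams, simulate_detection_histories


def bare_data(y):
    y = np.asarray(y, dtype=float)
    return DetectionData(y, pd.DataFrame(index=range(y.shape[0])))


def enumeration_loglik(data, beta, alpha, psi_cov=(), p_cov=()):
    """Brute-force marginalization over every latent occupancy vector
    z in {0,1}^S (independent oracle, feasible for <= 10 sites)."""
    from enmoccu.occupancy import _design_matrices
    X, W = _design_matrices(data, psi_cov, p_cov)
    psi = expit(X @ np.asarray(beta, float))
    p = expit(W @ np.asarray(alpha, float))
    n = data.n_sites
    total_by_site = np.zeros(n)
    for i in range(n):
        site_total = 0.0
        for z in (0, 1):
            pz = psi[i] if z else 1.0 - psi[i]
            lik = 1.0
            for j in range(data.n_occasions):
                if not data.conducted[i, j]:
                    continue
                pij = p[i, j] if z else 0.0
                lik *= pij if data.y[i, j] == 1 else 1.0 - pij
            site_total += pz * lik
        total_by_site[i] = site_total
    return float(np.sum(np.log(total_by_site)))


# ---------------------------------------------------------------------------
# likelihood

def test_loglik_hand_computed_histories():
    # psi = p = 0.5: history [1,1] -> 0.5 * 0.25; history [0,0] -> 0.5*0.25 + 0.5
    d11 = bare_data([[1, 1]])
    assert occupancy_loglik(d11, [0.0], [0.0]) == pytest.approx(np.log(0.125))
    d00 = bare_data([[0, 0]])
    assert occupancy_loglik(d00, [0.0], [0.0]) == pytest.approx(np.log(0.625))


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_loglik_equals_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    n, J = int(rng.integers(2, 10)), int(rng.integers(2, 6))
    site = pd.DataFrame({"x": rng.normal(size=n)})
    survey = {"w": rng.normal(size=(n, J))}
    y = rng.integers(0, 2, size=(n, J)).astype(float)
    miss = rng.random((n, J)) < 0.15
    miss[:, 0] = False  # keep every site surveyed at least once
    y[miss] = np.nan
    data = DetectionData(y, site, survey)
    beta = rng.normal(0, 1, 2)
    alpha = rng.normal(0, 1, 2)
    ll = occupancy_loglik(data, beta, alpha, ["x"], ["w"])
    oracle = enumeration_loglik(data, beta, alpha, ["x"], ["w"])
    assert abs(ll - oracle) < 1e-10


def test_missing_occasions_contribute_nothing():
    with_missing = bare_data([[1, np.nan, 0]])
    without = bare_data([[1, 0]])
    assert occupancy_loglik(with_missing, [0.3], [-0.2]) == \
        pytest.approx(occupancy_loglik(without, [0.3], [-0.2]))


# ---------------------------------------------------------------------------
# fitting

def test_zero_detections_flagged():
    data = bare_data(np.zeros((12, 4)))
    fit = OccupancyModel(data).fit(n_restarts=2)
    assert not fit.converged
    assert "identifiable" in fit.flagged_reason


def test_aicc_small_sample_arithmetic():
    # n = 30 sites, K = 3: AICc - AIC = 2*3*4/26 exactly
    rng = np.random.default_rng(3)
    y = (rng.random((30, 5)) < 0.3).astype(float)
    y[0, 0] = 1.0
    site = pd.DataFrame({"x": rng.normal(size=30)})
    data = DetectionData(y, site)
    fit = OccupancyModel(data, psi_covariates=["x"]).fit(n_restarts=2)
    assert fit.K == 3
    aic = -2 * fit.llf + 2 * 3
    assert fit.aicc - aic == pytest.approx(24.0 / 26.0, abs=1e-12)


def test_model_label_format(detection_data):
    m = OccupancyModel(detection_data, psi_covariates=["Veg_H"],
                       p_covariates=["N_obj"])
    assert m.label == "p(N_obj) psi(Veg_H)"


def test_standardization_round_trip(detection_data):
    std = detection_data.standardize()
    x = np.array([0.5, 2.0, 4.0])
    z = std.standardize_value("Veg_H", x)
    np.testing.assert_allclose(std.destandardize("Veg_H", z), x, atol=1e-12)
    assert std.site_covariates["Veg_H"].mean() == pytest.approx(0.0, abs=1e-9)
    assert std.site_covariates["Veg_H"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)


def test_estimated_psi_exceeds_naive_on_average():
    # with p < 1 the naive rate underestimates occupancy; check on means
    truth = TruthParams(beta_psi_true=[logit(0.5)], alpha_p_true=[logit(0.35)])
    psis, naives = [], []
    for seed in range(20):
        det = simulate_detection_histories(pd.DataFrame(index=range(100)), {},
                                           truth, 100, 4, seed=seed)
        fit = OccupancyModel(det, standardize=False).fit(n_restarts=1)
        if fit.converged:
            psis.append(expit(fit.beta_psi[0]))
            naives.append(naive_occupancy(det))
    assert np.mean(psis) > np.mean(naives)


# ---------------------------------------------------------------------------
# tables and two-stage selection

def test_model_table_reproduces_detection_stage_weights():
    class Stub:
        def __init__(self, label, k, aicc):
            self.label, self.K, self.aicc, self.converged = label, k, aicc, True
    fits = [Stub("p(N_obj) psi(.)", 3, 76.753), Stub("p(Veg_H) psi(.)", 3, 79.696),
            Stub("p(.)psi(.)", 2, 81.658), Stub("p(T_ground) psi(.)", 3, 82.961),
            Stub("p(Soil_moisture) psi(.)", 3, 83.163)]
    t = build_model_table(fits)
    np.testing.assert_allclose(t["AICcWt"], [0.714, 0.164, 0.061, 0.032, 0.029],
                               atol=0.002)
    np.testing.assert_allclose(t["Cum.Wt"].iloc[-1], 1.0, atol=1e-9)
    assert (t["Cum.Wt"].diff().dropna() >= 0).all()


def test_model_table_reproduces_occupancy_stage_weights():
    aicc = [70.090, 72.517, 72.536, 72.615, 72.619, 72.647, 72.906, 72.990,
            76.321, 76.462, 77.409, 77.867, 78.269, 78.803, 79.395, 89.356]
    from enmoccu.evaluation import akaike_deltas_weights
    _, w = akaike_deltas_weights(aicc)
    assert w[0] == pytest.approx(0.324, abs=0.002)
    assert w[1] == pytest.approx(0.096, abs=0.002)


def test_two_stage_trivial_candidates(detection_data):
    best, table, fits = two_stage_selection(detection_data, [("N_obj",)],
                                            [("Veg_H",)], n_restarts=2)
    assert best.model.p_covariates == ("N_obj",)
    assert best.model.psi_covariates == ("Veg_H",)
    assert len(table) == 1


def test_two_stage_table_rows_count(detection_data):
    occ_cands = [(), ("Veg_H",), ("N_obj",)]
    best, table, fits = two_stage_selection(detection_data, [(), ("N_obj",)],
                                            occ_cands, n_restarts=2)
    assert len(table) == len([f for f in fits if f.converged]) <= len(occ_cands)


def test_candidate_validator_rejects_three_covariates(detection_data):
    with pytest.raises(ValueError, match="two covariates"):
        two_stage_selection(detection_data, [("a", "b", "c")], [()])


# ---------------------------------------------------------------------------
# goodness of fit

def test_mb_chi2_matches_full_enumeration():
    """The observed + pooled form equals the sum over *all* possible
    histories (unobserved cells contribute (0-E)^2/E = E)."""
    rng = np.random.default_rng(11)
    y = (rng.random((12, 3)) < 0.4).astype(float)
    y[3, 1] = np.nan
    data = DetectionData(y, pd.DataFrame(index=range(12)))
    fit = OccupancyModel(data).fit(n_restarts=2)
    t = mb_chi2(fit)

    from enmoccu.occupancy import _design_matrices
    X, W = _design_matrices(data, (), ())
    psi = expit(X @ fit.beta_psi)
    p = expit(W @ fit.alpha_p)
    total = 0.0
    patterns = {}
    for i in range(12):
        patterns.setdefault(tuple(data.conducted[i]), []).append(i)
    for pattern, sites in patterns.items():
        occ_idx = [j for j, c in enumerate(pattern) if c]
        obs = {}
        for i in sites:
            h = tuple(int(data.y[i, j]) for j in occ_idx)
            obs[h] = obs.get(h, 0) + 1
        for h in itertools.product((0, 1), repeat=len(occ_idx)):
            e = 0.0
            for i in sites:
                cond = np.prod([p[i, j] if hv else 1 - p[i, j]
                                for j, hv in zip(occ_idx, h)])
                e += psi[i] * cond + (1 - psi[i]) * (sum(h) == 0)
            o = obs.get(h, 0)
            total += (o - e) ** 2 / e
    assert t == pytest.approx(total, abs=1e-8)


def test_gof_returns_valid_pvalue(detection_data):
    fit = OccupancyModel(detection_data, p_covariates=["N_obj"]).fit(n_restarts=2)
    t_obs, p, sims = parametric_bootstrap_gof(fit, n_sim=60, seed=1)
    assert t_obs > 0
    assert 0.0 < p <= 1.0
    assert sims.size >= 54  # at most 10% refit failures tolerated


def test_gof_detects_gross_heterogeneity():
    """Site heterogeneity in p that the constant model ignores inflates the
    observed chi-square relative to its bootstrap null (power check)."""
    rng = np.random.default_rng(12)
    small_ps = []
    for rep in range(5):
        n = 60
        p_site = np.where(rng.random(n) < 0.5, 0.95, 0.05)
        z = rng.random(n) < 0.8
        y = ((rng.random((n, 5)) < p_site[:, None]) & z[:, None]).astype(float)
        data = DetectionData(y, pd.DataFrame(index=range(n)))
        fit = OccupancyModel(data).fit(n_restarts=2)
        if not fit.converged:
            continue
        _, p, _ = parametric_bootstrap_gof(fit, n_sim=60, seed=rep)
        small_ps.append(p)
    assert np.median(small_ps) < 0.1


# ---------------------------------------------------------------------------
# prediction curves

def test_prediction_curve_flat_when_slope_zero(detection_data):
    fit = OccupancyModel(detection_data, psi_covariates=["Veg_H"]).fit(n_restarts=2)
    fit.params[1] = 0.0  # zero the slope
    curve = fit.predict_curve("Veg_H", np.linspace(0.5, 4.0, 5))
    np.testing.assert_allclose(curve["estimate"],
                               expit(fit.beta_psi[0]), rtol=1e-12)


def test_prediction_curve_declines_with_vegetation_height(detection_data):
    # the simulated truth has a negative vegetation-height effect on psi
    fit = OccupancyModel(detection_data, psi_covariates=["Veg_H"],
                         p_covariates=["N_obj"]).fit(n_restarts=3)
    assert fit.beta_psi[1] < 0
    curve = fit.predict_curve("Veg_H", np.array([1.0, 4.0]))
    assert curve["estimate"].iloc[1] < curve["estimate"].iloc[0]
    assert ((curve["lower"] > 0) & (curve["upper"] < 1)).all()
    assert (curve["lower"] <= curve["estimate"]).all()
    assert (curve["estimate"] <= curve["upper"]).all()


# ---------------------------------------------------------------------------
# naive occupancy

def test_naive_occupancy_counts_detected_sites():
    y = np.zeros((30, 5))
    y[:7, 0] = 1.0
    assert naive_occupancy(bare_data(y)) == pytest.approx(7 / 30)
    assert naive_occupancy(bare_data(np.zeros((5, 3)))) == 0.0


def test_naive_occupancy_approaches_one_with_many_occasions():
    truth = TruthParams(beta_psi_true=[30.0], alpha_p_true=[logit(0.5)])
    det = simulate_detection_histories(pd.DataFrame(index=range(200)), {},
                                       truth, 200, 12, seed=5)
    assert naive_occupancy(det) > 0.99


def test_simulation_respects_missingness(detection_data):
    fit = OccupancyModel(detection_data).fit(n_restarts=1)
    sim = fit.simulate(seed=3)
    np.testing.assert_array_equal(sim.conducted, detection_data.conducted)
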