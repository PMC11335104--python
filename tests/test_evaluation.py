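import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enmoccu.evaluation import (akaike_deltas_weights, akaike_table, binarize,
                                consensus_median, consensus_threshold,
                                maxent_aicc, omission_rate, partial_roc,
                                select_models, training_presence_threshold)
from enmoccu.maxent import MaxentModel


# ---------------------------------------------------------------------------
# Akaike machinery

def test_deltas_from_niche_candidate_aicc_column():
    aicc = [935.851, 936.684, 937.189, 937.527]
    delta, _ = akaike_deltas_weights(aicc)
    np.testing.assert_allclose(delta, [0.0, 0.833, 1.338, 1.676], atol=0.002)


def test_weights_from_detection_stage_aicc_column():
    aicc = [76.753, 79.696, 81.658, 82.961, 83.163]
    _, w = akaike_deltas_weights(aicc)
    np.testing.assert_allclose(w, [0.714, 0.164, 0.061, 0.032, 0.029], atol=0.002)


def test_single_model_table():
    t = akaike_table(["only"], [100.0], [3])
    assert t.loc[0, "Delta_AICc"] == 0.0
    assert t.loc[0, "AICcWt"] == pytest.approx(1.0)
    assert t.loc[0, "Cum.Wt"] == pytest.approx(1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 500), min_size=1, max_size=20))
def test_weights_sum_to_one_min_has_delta_zero(aicc):
    delta, w = akaike_deltas_weights(aicc)
    assert w.sum() == pytest.approx(1.0, abs=1e-9)
    assert delta.min() == 0.0
    assert w[np.argmin(aicc)] == w.max()


# ---------------------------------------------------------------------------
# omission and partial ROC

def test_omission_zero_when_test_above_threshold():
    train = np.linspace(0.1, 1.0, 40)
    test = np.full(10, 0.99)
    assert omission_rate(test, train, 5.0) == 0.0


def test_omission_calibrated_under_null():
    # train and test from the same distribution: E[omission] = E%
    rng = np.random.default_rng(0)
    oms = [omission_rate(rng.uniform(size=50), rng.uniform(size=200), 5.0)
           for _ in range(1000)]
    assert np.mean(oms) == pytest.approx(5.0, abs=2.0)


def test_partial_roc_perfect_separation():
    rng = np.random.default_rng(1)
    bg = rng.uniform(0, 0.5, 2000)
    test = rng.uniform(0.6, 1.0, 50)
    ratio, p = partial_roc(test, bg, e_percent=5.0, n_boot=200, seed=2)
    assert ratio == pytest.approx(2.0, abs=0.1)   # theoretical maximum
    assert p == 0.0


def test_partial_roc_null_behaviour():
    rng = np.random.default_rng(3)
    bg = rng.uniform(size=2000)
    test = rng.uniform(size=100)
    ratio, p = partial_roc(test, bg, e_percent=5.0, n_boot=500, seed=4)
    assert ratio == pytest.approx(1.0, abs=0.1)
    assert 0.2 <= p <= 0.8
    assert 0.0 <= p <= 1.0 and ratio >= 0.0


def test_partial_roc_rejects_constant_suitability():
    with pytest.raises(ValueError, match="constant"):
        partial_roc(np.full(20, 0.5), np.full(100, 0.5), n_boot=100)


# ---------------------------------------------------------------------------
# AICc for the niche model

def _uniform_model(n_bg=100, m=20, seed=0):
    rng = np.random.default_rng(seed)
    B = rng.uniform(0, 1, size=(n_bg, 2))
    F = B[rng.integers(0, n_bg, m)]
    model = MaxentModel(F, B, reg_multiplier=1e6,
                        feature_classes=["linear", "linear"])
    return model, model.fit(), F, B


def test_uniform_model_loglik_closed_form():
    _, res, F, B = _uniform_model(n_bg=100, m=20)
    aicc, k = maxent_aicc(res, F, B)
    assert k == 0
    # K = 0: AICc reduces to -2 * n * ln(1/N)
    assert aicc == pytest.approx(2 * 20 * np.log(100), rel=1e-9)


def test_small_sample_correction_arithmetic():
    # K=10, n=54: AICc - AIC = 2*10*11/43
    assert 2 * 10 * 11 / (54 - 10 - 1) == pytest.approx(5.116, abs=0.001)


def test_aicc_ranking_matches_formula_oracle():
    rng = np.random.default_rng(5)
    B = rng.uniform(0, 1, size=(300, 2))
    w = np.exp(B @ np.array([2.0, -1.0]))
    F = B[rng.choice(300, 60, p=w / w.sum())]
    rows = []
    for reg in (0.5, 2.0):
        res = MaxentModel(F, B, reg_multiplier=reg,
                          feature_classes=["linear", "linear"]).fit()
        aicc, k = maxent_aicc(res, F, B)
        ll = np.log(res.predict_raw(F) / res.predict_raw(B).sum()).sum()
        oracle = 2 * k - 2 * ll + 2 * k * (k + 1) / (60 - k - 1)
        assert aicc == pytest.approx(oracle, rel=1e-12)
        rows.append(aicc)
    assert rows[0] != rows[1]


def test_aicc_undefined_when_n_too_small():
    _, res, F, B = _uniform_model()
    res.lambda_ = np.array([0.5, -0.5])  # force K = 2
    aicc, k = maxent_aicc(res, F[:3], B)
    assert k == 2 and np.isnan(aicc)


# ---------------------------------------------------------------------------
# selection

def _metrics(rows):
    return pd.DataFrame(rows, columns=["Model", "Mean AUC ratio", "Pval pROC",
                                       "Omission rate (%)", "AICc"])


def test_selection_four_survivors():
    # mirrors the published scenario: many candidates, four clear winners
    rows = [("M_0.5_F_lq_set_2", 1.787, 0.0, 0.0, 935.851),
            ("M_0.6_F_lq_set_2", 1.791, 0.0, 0.0, 936.684),
            ("M_0.3_F_lq_set_2", 1.777, 0.0, 0.0, 937.189),
            ("M_0.7_F_lq_set_2", 1.795, 0.0, 0.0, 937.527),
            ("M_1_F_l_set_1", 1.5, 0.0, 0.0, 950.0),      # fails delta
            ("M_2_F_q_set_1", 1.6, 0.0, 12.0, 930.0),     # fails omission
            ("M_3_F_lq_set_1", 0.9, 0.6, 0.0, 920.0)]     # fails pROC
    sel = select_models(_metrics(rows))
    assert sel == ["M_0.5_F_lq_set_2", "M_0.6_F_lq_set_2",
                   "M_0.3_F_lq_set_2", "M_0.7_F_lq_set_2"]


def test_selection_single_and_empty():
    assert select_models(_metrics([("a", 1.5, 0.0, 1.0, 100.0)])) == ["a"]
    assert select_models(_metrics([("a", 1.5, 0.0, 9.0, 100.0),
                                   ("b", 1.2, 0.0, 5.0, 90.0)])) == []


# ---------------------------------------------------------------------------
# consensus and thresholding

def test_consensus_identity_and_median():
    g = np.array([[0.2, 0.7]])
    np.testing.assert_array_equal(consensus_median([g]), g)
    out = consensus_median([np.full((2, 2), 0.2), np.full((2, 2), 0.5),
                            np.full((2, 2), 0.9)])
    np.testing.assert_allclose(out, 0.5)


def test_consensus_even_count_matches_sort_oracle():
    rng = np.random.default_rng(6)
    grids = [rng.uniform(size=(5, 5)) for _ in range(4)]
    out = consensus_median(grids)
    stacked = np.sort(np.stack(grids), axis=0)
    np.testing.assert_allclose(out, (stacked[1] + stacked[2]) / 2, rtol=1e-12)


def test_consensus_nodata_propagates():
    a = np.array([[0.1, np.nan]])
    b = np.array([[0.3, 0.5]])
    out = consensus_median([a, b])
    assert np.isnan(out[0, 1]) and out[0, 0] == pytest.approx(0.2)


def test_threshold_averaging_to_0_096():
    # model thresholds {0.08, 0.10, 0.10, 0.104} average to 0.096
    trains = [np.full(10, v) for v in (0.08, 0.10, 0.10, 0.104)]
    assert consensus_threshold(trains, 10.0) == pytest.approx(0.096)


def test_tenth_percentile_leaves_at_most_ten_percent_below():
    rng = np.random.default_rng(7)
    train = rng.uniform(size=54)
    tau = training_presence_threshold(train, 10.0)
    assert np.mean(train < tau) <= 0.10 + 1.0 / 54


def test_binarize_threshold_zero_and_ties():
    grid = np.array([[0.0, 0.5], [np.nan, 1.0]])
    bm = binarize(grid, 0.0)
    assert bm.n_presence == 3 and np.isnan(bm.grid[1, 0])
    bm2 = binarize(grid, 0.5)   # tie at 0.5 -> presence
    assert bm2.grid[0, 1] == 1.0


def test_binary_area_monotone_in_threshold():
    rng = np.random.default_rng(8)
    grid = rng.uniform(size=(30, 30))
    counts = [binarize(grid, t).n_presence for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
    assert counts == sorted(counts, reverse=True)
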