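import numpy as np
import pytest
from scipy.special import logsumexp

from enmoccu.maxent import (Candidate, DataSplit, FeatureSpec, MaxentModel,
                            candidate_id, default_beta, make_features,
                            run_candidate_grid)
from enmoccu.prep import OccurrenceSet
import pandas as pd


def simple_spec(n_layers=1, combination="lq"):
    return FeatureSpec(combination=combination,
                       layer_names=[f"v{i}" for i in range(n_layers)],
                       lower=np.full(n_layers, 10.0),
                       upper=np.full(n_layers, 30.0))


# ---------------------------------------------------------------------------
# features

def test_feature_scaling_midpoint():
    spec = simple_spec()
    f = spec.transform(np.array([[20.0]]))
    assert f[0, 0] == pytest.approx(0.5)     # linear
    assert f[0, 1] == pytest.approx(0.25)    # quadratic


def test_lq_feature_count():
    spec = simple_spec(n_layers=4)
    f = spec.transform(np.full((3, 4), 15.0))
    assert f.shape == (3, 8)
    assert spec.feature_names == [f"v{i}" for i in range(4)] + \
        [f"v{i}^2" for i in range(4)]


def test_projection_values_clamp():
    spec = simple_spec()
    f = spec.transform(np.array([[5.0], [50.0]]))
    np.testing.assert_allclose(f[0], [0.0, 0.0])
    np.testing.assert_allclose(f[1], [1.0, 1.0])


def test_constant_layer_rejected():
    with pytest.raises(ValueError, match="v0"):
        FeatureSpec(combination="l", layer_names=["v0"],
                    lower=np.array([2.0]), upper=np.array([2.0]))


def test_default_beta_interpolates_and_clamps():
    assert default_beta("linear", 10) == pytest.approx(1.0)
    assert default_beta("linear", 100) == pytest.approx(0.05)
    assert default_beta("linear", 1000) == pytest.approx(0.05)
    assert default_beta("linear", 30) > default_beta("linear", 100)
    assert default_beta("quadratic", 17) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# fitting

def _gibbs_sample(lam_star, n_bg=2000, m=2000, seed=0):
    rng = np.random.default_rng(seed)
    bg = rng.uniform(0, 1, size=(n_bg, len(lam_star)))
    w = np.exp(bg @ np.asarray(lam_star))
    w = w / w.sum()
    idx = rng.choice(n_bg, size=m, p=w)
    return bg[idx], bg


def test_full_shrinkage_limit():
    F, B = _gibbs_sample([1.0, -0.5], n_bg=200, m=50, seed=1)
    res = MaxentModel(F, B, reg_multiplier=1e6,
                      feature_classes=["linear", "linear"]).fit()
    np.testing.assert_array_equal(res.lambda_, 0.0)
    raw = res.predict_raw(B)
    np.testing.assert_allclose(raw, 1.0 / 200, rtol=1e-12)
    assert res.entropy_H == pytest.approx(np.log(200), abs=1e-9)


def test_parameter_recovery_two_features():
    lam_star = np.array([2.0, -1.0])
    F, B = _gibbs_sample(lam_star, n_bg=2000, m=2000, seed=2)
    res = MaxentModel(F, B, reg_multiplier=0.1,
                      feature_classes=["linear", "linear"]).fit()
    np.testing.assert_allclose(res.lambda_, lam_star, atol=0.25)


def test_duplicated_presences_leave_fit_unchanged():
    """The log loss averages over presences, so duplicating the presence
    list leaves it (and, once the m-dependent default penalty is pinned,
    the fit) unchanged."""
    F, B = _gibbs_sample([1.5, 0.5], n_bg=400, m=60, seed=3)
    m1 = MaxentModel(F, B, reg_multiplier=1.0,
                     feature_classes=["linear", "linear"])
    m2 = MaxentModel(np.vstack([F, F]), B, reg_multiplier=1.0,
                     feature_classes=["linear", "linear"])
    m2.penalty = m1.penalty.copy()  # pin the penalty: compare pure losses
    theta = np.array([0.7, -0.3])
    assert m1._smooth_value_grad(theta)[0] == \
        pytest.approx(m2._smooth_value_grad(theta)[0], rel=1e-12)
    np.testing.assert_allclose(m1.fit().lambda_, m2.fit().lambda_, atol=1e-4)


def test_raw_normalizes_and_orders():
    F, B = _gibbs_sample([1.0, 1.0], n_bg=500, m=200, seed=4)
    res = MaxentModel(F, B, reg_multiplier=0.5,
                      feature_classes=["linear", "linear"]).fit()
    raw = res.predict_raw(B)
    assert abs(raw.sum() - 1.0) < 1e-9
    eta = B @ res.lambda_
    assert np.argmax(raw) == np.argmax(eta)


def test_cloglog_uniform_value_and_rank():
    F, B = _gibbs_sample([1.0, -1.0], n_bg=300, m=80, seed=5)
    res = MaxentModel(F, B, reg_multiplier=1e6,
                      feature_classes=["linear", "linear"]).fit()
    cl = res.predict_cloglog(B)
    np.testing.assert_allclose(cl, 1.0 - np.exp(-1.0), rtol=1e-9)
    res2 = MaxentModel(F, B, reg_multiplier=0.5,
                       feature_classes=["linear", "linear"]).fit()
    raw = res2.predict_raw(B)
    cl2 = res2.predict_cloglog(B)
    np.testing.assert_array_equal(np.argsort(raw), np.argsort(cl2))
    # spot-check the transform algebra on three cells
    for i in (0, 10, 200):
        assert cl2[i] == pytest.approx(1 - np.exp(-np.exp(res2.entropy_H) * raw[i]),
                                       rel=1e-12)


def test_matches_exhaustive_grid_search_on_tiny_background():
    """The proximal fit agrees with brute-force minimization of the same
    penalized loss over a lambda grid (step 0.01) on a 20-cell background."""
    rng = np.random.default_rng(6)
    B = rng.uniform(0, 1, size=(20, 2))
    w = np.exp(B @ np.array([1.5, -1.0]))
    idx = rng.choice(20, size=30, p=w / w.sum())
    F = B[idx]
    model = MaxentModel(F, B, reg_multiplier=1.0,
                        feature_classes=["linear", "linear"])
    res = model.fit()

    grid = np.arange(-3.0, 3.0001, 0.01)
    l1, l2 = np.meshgrid(grid, grid, indexing="ij")
    lams = np.column_stack([l1.ravel(), l2.ravel()])
    mean_pres = F.mean(axis=0)
    vals = (-lams @ mean_pres + logsumexp(B @ lams.T, axis=0)
            + np.abs(lams) @ model.penalty)
    best = lams[np.argmin(vals)]
    np.testing.assert_allclose(res.lambda_, best, atol=0.02)


def test_sparsity_weakly_monotone_in_regularization():
    F, B = _gibbs_sample([2.0, -1.0, 0.5, 0.0], n_bg=500, m=60, seed=7)
    classes = ["linear"] * 4
    nnz = []
    for reg in (0.1, 0.5, 1.0, 2.0, 5.0):
        res = MaxentModel(F, B, reg_multiplier=reg, feature_classes=classes).fit()
        nnz.append(res.n_params)
    assert all(a >= b for a, b in zip(nnz, nnz[1:]))


# ---------------------------------------------------------------------------
# candidate grid

def test_data_split_partitions():
    split = DataSplit(n=54, fraction=0.2, seed=3)
    assert len(split.test_ids) == 11
    assert len(split.train_ids) == 43
    assert set(split.train_ids) | set(split.test_ids) == set(range(54))
    assert not set(split.train_ids) & set(split.test_ids)


def test_candidate_grid_ids_and_counts(env_stack):
    from enmoccu.synthetic import TruthParams, sample_occurrences
    occ = sample_occurrences(env_stack, TruthParams(lambda_true=[2, 0, -1, 0]),
                             n=60, seed=8)
    set1 = env_stack.subset(["env_1", "env_3"], set_id="set_1")
    set2 = env_stack.subset(["env_2", "env_4"], set_id="set_2")
    split = DataSplit(n=60, fraction=0.2, seed=0)
    cands = run_candidate_grid(occ, [set1, set2], [0.5], ["lq"], split)
    assert len(cands) == 2
    assert {c.model_id for c in cands} == {"M_0.5_F_lq_set_1", "M_0.5_F_lq_set_2"}
    bigger = run_candidate_grid(occ, [set1, set2], [0.5, 1.0, 2.0],
                                ["l", "q", "lq"], split)
    assert len(bigger) == 18
    assert candidate_id(0.5, "lq", "set_2") == "M_0.5_F_lq_set_2"
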