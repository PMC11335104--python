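import numpy as np
import pandas as pd
import pytest

from enmoccu.occupancy import DetectionData
from enmoccu.raster import EnvStack, GridTransform
from enmoccu.synthetic import (LandscapeSpec, TruthParams, generate_env_stack,
                               default_site_covariates,
                               simulate_detection_histories)


@pytest.fixture(scope="session")
def landscape_spec():
    return LandscapeSpec(n_rows=60, n_cols=60, cell_size=0.01,
                         autocorr_range=5.0, n_layers=4,
                         correlated_pair_rho=0.92, seed=11)


@pytest.fixture(scope="session")
def env_stack(landscape_spec):
    return generate_env_stack(landscape_spec)


@pytest.fixture(scope="session")
def small_transform():
    return GridTransform(origin_lon=-76.0, origin_lat=7.0, cell_size=0.01,
                         n_rows=20, n_cols=20)


@pytest.fixture()
def detection_data():
    """30 sites x 5 occasions with 5 missing surveys, simulated from known
    logit-linear occupancy/detection truth on standardized covariates."""
    rng = np.random.default_rng(21)
    site = pd.DataFrame({
        "Veg_H": rng.normal(0, 1, 30),
        "N_obj": rng.normal(0, 1, 30),
    })
    truth = TruthParams(beta_psi_true=[0.0, -1.0, 0.0],
                        alpha_p_true=[0.0, 1.0],
                        missing_fraction=5.0 / 150.0)
    survey = {"N_obj": np.repeat(site["N_obj"].to_numpy()[:, None], 5, axis=1)}
    return simulate_detection_histories(site, survey, truth, 30, 5, seed=22)
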