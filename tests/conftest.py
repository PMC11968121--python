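import numpy as np
import pytest

import twinpath as tp


@pytest.fixture(scope="session")
def study_model():
    """Study-structure generating model (C innovations at occasions 1-2 only)."""
    return tp.default_truth()


@pytest.fixture(scope="session")
def interior_model():
    """Interior-point generating model for recovery/calibration checks."""
    return tp.interior_truth()


@pytest.fixture(scope="session")
def study_pairs(study_model):
    """One study-conditions dataset: n=1500/zygosity, cohort missingness."""
    model, truth = study_model
    cfg = tp.SimulationConfig(model, truth, n_mz=1500, n_dz=1500, seed=20240917)
    pairs, _ = tp.simulate_pairs(cfg)
    return pairs


@pytest.fixture(scope="session")
def complete_pairs(interior_model):
    """Complete-record dataset from the interior-point model."""
    model, truth = interior_model
    cfg = tp.SimulationConfig(model, truth, n_mz=1200, n_dz=1200, seed=7,
                              missingness=None)
    pairs, _ = tp.simulate_pairs(cfg)
    return pairs


def mc_cov_check(draws: np.ndarray, implied: np.ndarray, n_se: float = 4.0):
    """Assert the empirical covariance of draws matches an implied matrix
    elementwise within n_se Monte-Carlo standard errors."""
    n = draws.shape[0]
    centred = draws - draws.mean(axis=0)
    prod = centred[:, :, None] * centred[:, None, :]
    emp = prod.mean(axis=0) * n / (n - 1)
    se = prod.std(axis=0) / np.sqrt(n)
    dev = np.abs(emp - implied) / np.maximum(se, 1e-12)
    assert dev.max() < n_se, f"max deviation {dev.max():.2f} MC SEs"
    return dev.max()
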