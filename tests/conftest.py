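import numpy as np
import pytest

from latentshift import (
    LongitudinalDataset,
    ModelSpec,
    Parameters,
    Subject,
    Visit,
)
from latentshift.covariance import VarianceParams
from latentshift.simulate import SimulationConfig, default_true_parameters, simulate_dataset


@pytest.fixture(scope="session")
def true_params() -> Parameters:
    return default_true_parameters()


@pytest.fixture(scope="session")
def basic_spec() -> ModelSpec:
    return ModelSpec()


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject cohort from the default generative model (seed 42)."""
    cfg = SimulationConfig(n_subjects=60, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit(small_cohort, basic_spec):
    from latentshift import fit_ml

    dataset, _ = small_cohort
    return fit_ml(dataset, basic_spec)


@pytest.fixture
def tiny_dataset():
    """Three hand-written subjects across two groups."""
    subjects = [
        Subject("a", "cognitively normal", {"age": 70.0},
                [Visit(0.0, 9.5), Visit(6.0, 10.1), Visit(12.0, 9.8)]),
        Subject("b", "dementia", {"age": 76.0},
                [Visit(0.0, 31.0), Visit(12.0, 36.5)]),
        Subject("c", "MCI (late)", {"age": 72.0},
                [Visit(0.0, 17.0)]),
    ]
    return LongitudinalDataset(subjects, covariate_names=("age",))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mid_variance():
    return VarianceParams(tau2=576.0, sigma2_bm=0.08, sigma2_0=4.0,
                          sigma2_eps=6.25, rho=3.6)
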