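import numpy as np
import pytest

from twinfiml import (
    ACEParams,
    CovariateStructure,
    JointModel,
    MissingnessSpec,
    RegressionWeights,
    SimulationConfig,
    impose_missingness,
    simulate_dataset,
    solve_equal_beta,
)


@pytest.fixture(scope="session")
def ace():
    """The generating ACE components of the simulation design."""
    return ACEParams(0.5, 0.3, 0.2, mu_y=0.0)


@pytest.fixture(scope="session")
def cov5():
    """Five-covariate exchangeable structure (variance 1, corr .1 / .5)."""
    return CovariateStructure.exchangeable(5)


@pytest.fixture(scope="session")
def design_model(ace, cov5):
    """Joint model at the simulation-design truth (39% variance explained)."""
    return JointModel(ace, cov5, solve_equal_beta(0.39, ace, cov5))


@pytest.fixture(scope="session")
def small_complete_dataset():
    """Complete two-covariate dataset, 500 pairs."""
    config = SimulationConfig(
        n_mz=140, n_dz=360, cov=CovariateStructure.exchangeable(2)
    )
    return simulate_dataset(config, 714)


@pytest.fixture(scope="session")
def small_mar_dataset(small_complete_dataset):
    """Same dataset with 10% of covariate entries deleted MAR."""
    return impose_missingness(
        small_complete_dataset, MissingnessSpec("MAR", 0.10), 715
    )


def random_valid_model(rng: np.random.Generator, K: int) -> JointModel:
    """A random joint model satisfying every structural invariant."""
    ace = ACEParams(*rng.uniform(0.05, 1.0, size=3), mu_y=rng.normal())
    w = rng.normal(size=(K, K))
    sw = w @ w.T + 0.1 * np.eye(K)
    b = rng.normal(size=(K, K)) * 0.5
    sb = b @ b.T
    cov = CovariateStructure(K, rng.normal(size=K), sw, sb)
    return JointModel(ace, cov, RegressionWeights(rng.normal(size=K)))
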