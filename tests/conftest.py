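import numpy as np
import pytest

from biosorb import (
    METALS,
    BatchDesign,
    NoiseSpec,
    TrueIsotherm,
    generate_isotherm,
    paper_like_design,
)


@pytest.fixture(scope="session")
def cd_design() -> BatchDesign:
    return paper_like_design("Cd")


@pytest.fixture(scope="session")
def langmuir_truth() -> TrueIsotherm:
    return TrueIsotherm("langmuir", (170.0, 0.01))


@pytest.fixture(scope="session")
def freundlich_truth() -> TrueIsotherm:
    return TrueIsotherm("freundlich", (10.0, 2.0))


@pytest.fixture(scope="session")
def exact_cd_langmuir(cd_design, langmuir_truth):
    """Noise-free Cd-like Langmuir dataset (exactly collinear once linearized)."""
    return generate_isotherm(cd_design, langmuir_truth, NoiseSpec(0.0, 0))


@pytest.fixture(scope="session")
def exact_cd_freundlich(cd_design, freundlich_truth):
    return generate_isotherm(cd_design, freundlich_truth, NoiseSpec(0.0, 0))


def random_regression_instance(rng: np.random.Generator, max_obs=5, max_pred=2):
    """Small random instance for LP-vs-oracle comparisons."""
    n_obs = int(rng.integers(3, max_obs + 1))
    n_pred = int(rng.integers(1, max_pred + 1))
    x = rng.uniform(-3, 3, size=(n_obs, n_pred))
    beta = rng.uniform(-2, 2, size=n_pred)
    y = x @ beta + rng.normal(0, 0.5, size=n_obs)
    from biosorb import RegressionData

    return RegressionData(x, y)
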