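import numpy as np
import pytest

from pherograd import (
    GradientShape,
    NoiseConfig,
    PopulationConfig,
    ResponseParams,
    generate_dataset,
)

#: fitted gradient of the half-domain experiment, used as generator truth
STUDY_SHAPE = GradientShape(lambda_=735.0, C=1.45)
RESP_G = ResponseParams(n=1, A=1.0, b=0.1)
RESP_M = ResponseParams(n=3, A=25.0, b=5.0)


@pytest.fixture(scope="session")
def study_shape():
    return STUDY_SHAPE


@pytest.fixture(scope="session")
def resp_g():
    return RESP_G


@pytest.fixture(scope="session")
def resp_m():
    return RESP_M


@pytest.fixture(scope="session")
def default_noise():
    return NoiseConfig()  # gfp_cv=0.30, length_sd=1.5


@pytest.fixture(scope="session")
def study_pop():
    return PopulationConfig()  # 6,686 receivers over ±2,700 μm


@pytest.fixture(scope="session")
def small_pop():
    return PopulationConfig(n_receivers=1500, n_emitters=500)


@pytest.fixture(scope="session")
def noisy_dataset(study_pop, study_shape, resp_g, resp_m, default_noise):
    """One study-scale noisy table, shared across read-only tests."""
    return generate_dataset(
        study_pop, study_shape, RESP_G, RESP_M, default_noise, seed=42
    )


@pytest.fixture(scope="session")
def noiseless_dataset(study_pop, study_shape):
    noise = NoiseConfig(gfp_cv=0.0, length_sd=0.0)
    return generate_dataset(
        study_pop, study_shape, RESP_G, RESP_M, noise, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
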