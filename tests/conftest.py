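import numpy as np
import pytest

from screenlasso.schema import default_schema, predictor_names
from screenlasso.simulate import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def predictors(schema):
    return predictor_names(schema)


@pytest.fixture(scope="session")
def survey487():
    """Default synthetic survey at the study's sample size."""
    return generate_dataset(GeneratorConfig(n=487, seed=11))


@pytest.fixture(scope="session")
def survey10k():
    """Large synthetic survey for moment/fidelity checks."""
    return generate_dataset(GeneratorConfig(n=10_000, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
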