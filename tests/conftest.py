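import numpy as np
import pytest

from evosteer import synthetic_data as sd


@pytest.fixture(scope="session")
def default_spec():
    return sd.generate_population_spec()


@pytest.fixture(scope="session")
def default_dataset(default_spec):
    """One full synthetic experiment at default (study) conditions."""
    return sd.simulate_experiment(default_spec, sd.ExperimentDesign(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
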