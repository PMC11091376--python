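import numpy as np
import pytest

from morphanat.synthetic import (
    InjuryGeneratorSpec,
    PopulationSpec,
    generate_baseline_mesh,
    generate_injury_dataset,
    generate_population,
)


@pytest.fixture(scope="session")
def baseline_mesh():
    """Default two-part head mesh plus its companion skull surface."""
    return generate_baseline_mesh()


@pytest.fixture(scope="session")
def noiseless_population():
    """Default-size population with zero landmark noise (exact linear truth)."""
    return generate_population(PopulationSpec(noise_sigma=0.0, seed=7))


@pytest.fixture(scope="session")
def default_injury_dataset():
    return generate_injury_dataset(InjuryGeneratorSpec(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
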