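import numpy as np
import pytest

from heliscan import PlantSpec, ScanParameters, make_planted_genome


@pytest.fixture(scope="session")
def default_params():
    return ScanParameters()


@pytest.fixture(scope="session")
def planted():
    """A 5-cassette planted genome with its truth table."""
    spec = PlantSpec(n_cassettes=5, background_length=8000, seed=11)
    return make_planted_genome(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)


def random_seq(rng, length, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(list("ATGC"), size=length, p=p))
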