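import numpy as np
import pytest
from hypothesis import settings

from woodsim.species import default_herb_species, default_woody_species

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def woody():
    return default_woody_species()


@pytest.fixture(scope="session")
def herbs_table():
    return default_herb_species()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


class MeanRng:
    """Deterministic stand-in generator: every normal draw returns its mean."""

    def normal(self, loc, scale):
        return loc

    def uniform(self, lo, hi):
        return (lo + hi) / 2.0

    def random(self):
        return 0.5


@pytest.fixture()
def mean_rng():
    return MeanRng()
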