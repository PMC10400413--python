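import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True)
settings.load_profile("default")

from gocls import Notebook, make_linear_teacher, sample_examples
from gocls.experiments import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Deterministic small fixture bundle (tiny teacher/examples/notebook)."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def snr4_teacher():
    return make_linear_teacher(4.0, 100, seed=11)


@pytest.fixture(scope="session")
def snr4_data(snr4_teacher):
    return sample_examples(snr4_teacher, 100, seed=12)


@pytest.fixture(scope="session")
def encoded_notebook(snr4_data):
    """P=100 examples encoded in an M=2000, a=0.05 notebook."""
    nb = Notebook(2000, 0.05, 100, seed=13)
    nb.encode(snr4_data)
    return nb


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
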