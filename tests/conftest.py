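import numpy as np
import pytest

from targetclp.io_formats import ProteinRecord
from targetclp.synthetic_data import SynthSpec, gen_energy_matrix, gen_sequences


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def energy_matrix():
    return gen_energy_matrix(seed=3)


@pytest.fixture(scope="session")
def records():
    spec = SynthSpec(n_sequences=6, length_range=(20, 40), seed=11)
    return gen_sequences(spec)


@pytest.fixture
def record():
    return ProteinRecord("p1", "MKVLAWRHETNDCQGISPYF")
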