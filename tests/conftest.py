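import numpy as np
import pytest

from tsss.scoring import STANDARD_AMINO_ACIDS, load_blosum62


@pytest.fixture(scope="session")
def blosum62():
    return load_blosum62()


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def random_protein(rng, length):
    return "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=length))
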