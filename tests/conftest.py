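import numpy as np
import pytest

from sipquant import PeptideIon, composition_of


@pytest.fixture(scope="session")
def vvn_ion():
    """The doubly charged PAH-dioxygenase peptide used as the worked example."""
    return PeptideIon("VVNAEAGNAR", charge=2)


@pytest.fixture(scope="session")
def vvn_comp(vvn_ion):
    return composition_of(vvn_ion)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
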