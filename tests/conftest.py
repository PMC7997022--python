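import numpy as np
import pytest

from exomd.synthetic import za253_fixtures


@pytest.fixture(scope="session")
def za253():
    """(pedigree, genotype matrix, variants) of the packaged worked example."""
    return za253_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
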