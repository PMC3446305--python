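import numpy as np
import pytest

import varxome


@pytest.fixture(scope="session")
def small_genome():
    """100 kb genome with 3 genes, shared across tests."""
    genome, genes, repeats = varxome.make_genome(100_000, 3, seed=11)
    return genome, genes, repeats


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
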