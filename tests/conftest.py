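import numpy as np
import pytest

from chemotrace import load_bundled_signatures
from chemotrace.simulate import simulate_reference


@pytest.fixture(scope="session")
def signatures():
    return load_bundled_signatures()


@pytest.fixture(scope="session")
def baseline(signatures):
    return signatures.subset(["SBS1", "SBS5", "SBS40"])


@pytest.fixture(scope="session")
def small_reference():
    """A deterministic 100 kb single-contig reference."""
    return simulate_reference(n_contigs=1, contig_length=100_000, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
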