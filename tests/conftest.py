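import numpy as np
import pytest

from ssrscout.synthetic_data import generate_study


@pytest.fixture(scope="session")
def study():
    """Small synthetic study shared across tests: 9 genes on 3 contigs,
    planted hotspot clusters and scattered SSR arrays."""
    contigs, genes, truth = generate_study(1)
    return contigs, genes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
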