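import numpy as np
import pytest

from orthostruct import EvolutionConfig, progressive_msa, simulate_family


@pytest.fixture(scope="session")
def bundle():
    """Default eight-taxon family (six monocots, two dicots), seed 1."""
    return simulate_family(EvolutionConfig(seed=1))


@pytest.fixture(scope="session")
def family_msa(bundle):
    """Progressive protein MSA of the default family."""
    return progressive_msa([t.protein for t in bundle.taxa])


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
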