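import numpy as np
import pytest

from rgwas.simulate import SimDesign, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Structured dataset small enough for exact-mode scans in tests."""
    return simulate_dataset(
        SimDesign(n=300, m_snps=150, h2_main=0.3, contamination_rate=0.05),
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
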