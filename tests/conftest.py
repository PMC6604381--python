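import numpy as np
import pytest

from balli import CountMatrix, DesignPair


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_counts(rng):
    """30 genes x 6 samples with mildly varying library sizes."""
    means = rng.lognormal(4.0, 1.0, size=(30, 1)) * np.array([1, 1.3, 0.8, 1, 1.1, 0.9])
    counts = rng.poisson(means)
    return CountMatrix([f"g{i}" for i in range(30)], [f"s{j}" for j in range(6)], counts)


@pytest.fixture
def two_group_design():
    """Six samples, intercept-only Z, 3-vs-3 group dummy."""
    x = np.array([1.0, 1, 1, 0, 0, 0]).reshape(-1, 1)
    return DesignPair(Z=np.ones((6, 1)), X=x, M=2)
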