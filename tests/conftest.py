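import numpy as np
import pytest

from episis import GenotypeMatrix, PhenotypeVector


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_dataset():
    """Factory for random balanced case-control genotype fixtures."""

    def _make(n=60, L=20, seed=0, maf_low=0.1, maf_high=0.5):
        r = np.random.default_rng(seed)
        mafs = r.uniform(maf_low, maf_high, size=L)
        G = r.binomial(2, mafs, size=(n, L)).astype(np.int8)
        status = np.zeros(n, dtype=np.int8)
        status[: n // 2] = 1
        r.shuffle(status)
        if status.sum() in (0, n):  # force both groups
            status[0], status[-1] = 1, 0
        return GenotypeMatrix(G), PhenotypeVector(status)

    return _make
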