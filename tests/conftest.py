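import numpy as np
import pytest

from codak import CompositionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def random_composition(rng):
    """Factory for strictly positive random compositions (log-normal parts)."""

    def make(n=6, q=5, spread=1.0, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        raw = np.exp(r.normal(0.0, spread, size=(n, q)))
        return CompositionMatrix(raw / raw.sum(axis=1, keepdims=True))

    return make
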