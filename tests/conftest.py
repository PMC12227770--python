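import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def block_se(series, n_blocks=20):
    """Autocorrelation-aware standard error via block averaging."""
    series = np.asarray(series, dtype=float)
    blocks = np.array_split(series, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(np.std(means, ddof=1) / np.sqrt(len(means)))
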