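import numpy as np
import pytest

import eplclust as ec


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_partition(rng, n, k_max=None):
    """A random label vector over up to k_max groups (not necessarily canonical)."""
    k_max = k_max or max(2, n // 2)
    return rng.integers(1, k_max + 1, size=n)


def random_sample(rng, n, t, k_max=None):
    return ec.PartitionSample(
        np.stack([random_partition(rng, n, k_max) for _ in range(t)])
    )
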