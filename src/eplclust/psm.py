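"""Posterior similarity matrix utilities.

The posterior similarity matrix collects, for every pair of items, the
estimated posterior probability that they share a group.  Binder's expected
posterior loss depends on the sample only through this matrix, up to an
additive constant in the decision — which makes the matrix a convenient
independent cross-check of the expected-loss machinery, and the bridge to
the older pairwise-coclustering algorithms built on it.
"""

from __future__ import annotations

import numpy as np

from .partitions import PartitionSample, as_partition

__all__ = ["posterior_similarity", "binder_psm_objective"]


def posterior_similarity(sample: PartitionSample) -> np.ndarray:
    """Weighted co-clustering frequency matrix, shape (N, N).

    Entry (i, j) is the weighted fraction of sample rows in which items i and
    j carry the same label; symmetric, unit diagonal, entries in [0, 1].
    Cost O(T̃ · N²).
    """
    n = sample.n_items
    b = np.zeros((n, n), dtype=np.float64)
    for t in range(sample.n_draws):
        z = sample.labels[t]
        b += sample.weights[t] * (z[:, None] == z[None, :])
    b /= sample.total_weight
    return b


def binder_psm_objective(a, b: np.ndarray) -> float:
    """Binder objective in PSM form: Σ_{i<j} 1{a_i=a_j} (1 − 2 b_ij).

    Differs from the Binder expected posterior loss of ``a`` by an additive
    constant that does not depend on ``a``, so both rank candidate decisions
    identically.
    """
    a = as_partition(a)
    b = np.asarray(b, dtype=np.float64)
    if b.shape != (a.size, a.size):
        raise ValueError("similarity matrix shape does not match the partition")
    same = a[:, None] == a[None, :]
    iu = np.triu_indices(a.size, k=1)
    return float((same[iu] * (1.0 - 2.0 * b[iu])).sum())
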