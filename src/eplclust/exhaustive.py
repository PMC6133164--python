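"""Exhaustive expected-loss minimisation over all set partitions.

Only feasible for small N (the number of set partitions of N items is the
Bell number, which already exceeds 10^5 at N = 10 and has more than 100
decimal digits at N = 100), but on small instances it provides the exact
Bayes action and therefore a ground truth for validating the greedy
optimiser.  Losses are evaluated through their direct formulas, a route
disjoint from the incremental decomposition used by the greedy algorithm.
"""

from __future__ import annotations

import numpy as np
from sympy.utilities.iterables import multiset_partitions

from .compressor import compress_sample
from .partitions import PartitionSample, canonical_relabel

__all__ = ["all_partitions", "exhaustive_epl", "exhaustive_minimise"]

_MAX_EXHAUSTIVE_N = 12


def all_partitions(n: int) -> np.ndarray:
    """All set partitions of ``n`` items as canonical label rows (Bell(n), n)."""
    if not 1 <= n <= _MAX_EXHAUSTIVE_N:
        raise ValueError(f"exhaustive enumeration supported for 1 <= N <= {_MAX_EXHAUSTIVE_N}")
    rows = []
    for blocks in multiset_partitions(list(range(n))):
        labels = np.empty(n, dtype=np.int64)
        for g, block in enumerate(blocks, start=1):
            for item in block:
                labels[item] = g
        rows.append(canonical_relabel(labels))
    return np.asarray(rows)


def exhaustive_epl(sample: PartitionSample, loss) -> tuple[np.ndarray, np.ndarray]:
    """EPL of every set partition of the sample's items under one loss.

    Returns ``(candidates, epl)`` where ``candidates`` has shape
    (Bell(N), N) and ``epl[p]`` is the expected posterior loss of candidate
    ``p``.  Each loss is computed from the candidate/row contingency counts
    by its direct formula, vectorised across candidates.
    """
    from .losses import get_loss  # local import to avoid cycle at module load

    spec = get_loss(loss)
    comp = compress_sample(sample)
    n = comp.n_items
    cands = all_partitions(n)
    n_cand = cands.shape[0]
    a0 = cands - 1
    ka = a0.max(axis=1) + 1
    ka_max = int(ka.max())
    sizes = np.zeros((n_cand, ka_max), dtype=np.int64)
    np.add.at(sizes, (np.arange(n_cand)[:, None], a0), 1)

    def plogp(counts):
        p = counts.astype(np.float64) / n
        out = np.zeros_like(p)
        pos = p > 0
        out[pos] = p[pos] * np.log2(p[pos])
        return out

    if spec.name == "B":
        row_term = 0.5 * (sizes.astype(np.float64) ** 2).sum(axis=1)
    else:
        ha = -plogp(sizes).sum(axis=1)

    epl = np.zeros(n_cand)
    cand_idx = np.arange(n_cand)[:, None]
    for t in range(comp.n_draws):
        z0 = canonical_relabel(comp.labels[t]) - 1
        kz = int(z0.max()) + 1
        counts = np.zeros((n_cand, ka_max * kz), dtype=np.int64)
        np.add.at(counts, (cand_idx, a0 * kz + z0), 1)
        zsizes = np.bincount(z0, minlength=kz)
        if spec.name == "B":
            col_term = 0.5 * float((zsizes.astype(np.float64) ** 2).sum())
            vals = row_term + col_term - (counts.astype(np.float64) ** 2).sum(axis=1)
        else:
            hz = -plogp(zsizes).sum()
            haz = -plogp(counts).sum(axis=1)
            if spec.name == "VI":
                vals = 2.0 * haz - ha - hz
            elif spec.name == "NVI":
                mi = ha + hz - haz
                vals = np.where(haz > 0, 1.0 - mi / np.where(haz > 0, haz, 1.0), 0.0)
            else:  # NID
                mi = ha + hz - haz
                hmax = np.maximum(ha, hz)
                vals = np.where(hmax > 0, 1.0 - mi / np.where(hmax > 0, hmax, 1.0), 0.0)
        epl += comp.weights[t] * vals
    epl /= comp.total_weight
    return cands, epl


def exhaustive_minimise(sample: PartitionSample, loss) -> tuple[np.ndarray, float]:
    """The exact Bayes action and its EPL by enumeration (small N only)."""
    cands, epl = exhaustive_epl(sample, loss)
    best = int(np.argmin(epl))
    return cands[best].copy(), float(epl[best])
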