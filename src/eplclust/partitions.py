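"""Partitions, partition samples and contingency tables.

A partition of ``N`` items is encoded as a length-``N`` vector of positive
integer labels; two label vectors related by a permutation of the labels
denote the same partition.  The canonical form relabels groups by order of
first appearance, which makes equivalence testing a plain array comparison
and removes label-switching ambiguity from MCMC output.

All information-theoretic quantities use base-2 logarithms (values in bits)
with the convention ``x * log2(x) = 0`` at ``x = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy


__all__ = [
    "Partition",
    "PartitionSample",
    "ContingencyTable",
    "as_partition",
    "canonical_relabel",
    "partitions_equivalent",
    "contingency_table",
    "entropy",
    "entropy_from_counts",
    "joint_entropy",
    "mutual_information",
    "bell_number",
]


Partition = np.ndarray
"""Alias for a 1-D integer label vector (one label ≥ 1 per item)."""


def as_partition(labels) -> np.ndarray:
    """Validate and convert ``labels`` to a 1-D positive-integer array."""
    arr = np.asarray(labels)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("a partition must be a nonempty 1-D label vector")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
            arr = arr.astype(np.int64)
        else:
            raise ValueError("partition labels must be integers")
    if np.any(arr < 1):
        raise ValueError("partition labels must be positive integers (1-based)")
    return arr.astype(np.int64, copy=False)


def canonical_relabel(p) -> np.ndarray:
    """Relabel groups by order of first appearance.

    The first item gets label 1; each subsequent item gets either the label
    already assigned to its group or the next unused label.  Idempotent, and
    two label vectors are equivalent iff their canonical forms are equal.
    """
    arr = as_partition(p)
    _, first_idx, inverse = np.unique(arr, return_index=True, return_inverse=True)
    # rank of each unique label by position of first occurrence
    rank = np.empty(first_idx.size, dtype=np.int64)
    rank[np.argsort(first_idx)] = np.arange(first_idx.size)
    return rank[inverse] + 1


def partitions_equivalent(p, q) -> bool:
    """True iff ``p`` and ``q`` encode the same partition up to label permutation."""
    a, z = as_partition(p), as_partition(q)
    if a.size != z.size:
        raise ValueError(f"partitions have different lengths ({a.size} vs {z.size})")
    return bool(np.array_equal(canonical_relabel(a), canonical_relabel(z)))


@dataclass(frozen=True)
class PartitionSample:
    """A (possibly weighted) sample of ``T`` partitions of the same ``N`` items.

    Parameters
    ----------
    labels
        Integer array of shape ``(T, N)``; row ``t`` is one draw.
    weights
        Strictly positive multiplicities, shape ``(T,)``.  Defaults to 1 for
        every row (a raw MCMC sample); compression accumulates them.
    """

    labels: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.shape[0] == 0 or lab.shape[1] == 0:
            raise ValueError("sample must be a nonempty T x N label matrix")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("sample labels must be integers")
        if np.any(lab < 1):
            raise ValueError("sample labels must be positive integers")
        lab = lab.astype(np.int64, copy=False)
        if self.weights is None:
            w = np.ones(lab.shape[0], dtype=np.float64)
        else:
            w = np.asarray(self.weights, dtype=np.float64)
            if w.shape != (lab.shape[0],):
                raise ValueError("weights must have one entry per sample row")
            if np.any(w <= 0):
                raise ValueError("weights must be strictly positive")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "weights", w)

    @property
    def n_draws(self) -> int:
        return self.labels.shape[0]

    @property
    def n_items(self) -> int:
        return self.labels.shape[1]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-classification counts between two partitions of the same items.

    ``counts[g, h]`` is the number of items that the first partition places
    in group ``g+1`` and the second in group ``h+1``; margins are the group
    sizes of each partition.
    """

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or np.any(c < 0):
            raise ValueError("contingency counts must be a nonnegative 2-D array")
        object.__setattr__(self, "counts", c.astype(np.int64, copy=False))

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_items(self) -> int:
        return int(self.counts.sum())


def contingency_table(a, z) -> ContingencyTable:
    """Build the K_a x K_z contingency table between partitions ``a`` and ``z``."""
    ac = canonical_relabel(a) - 1
    zc = canonical_relabel(z) - 1
    if ac.size != zc.size:
        raise ValueError(f"partitions have different lengths ({ac.size} vs {zc.size})")
    ka = int(ac.max()) + 1
    kz = int(zc.max()) + 1
    counts = np.bincount(ac * kz + zc, minlength=ka * kz).reshape(ka, kz)
    return ContingencyTable(counts)


def entropy_from_counts(counts, n_items: int) -> float:
    """Entropy in bits of the distribution ``counts / n_items`` (0 log 0 = 0)."""
    c = np.asarray(counts, dtype=np.float64).ravel()
    c = c[c > 0]
    p = c / n_items
    return float(-(p * np.log2(p)).sum())


def entropy(p) -> float:
    """Entropy in bits of the group-size distribution of partition ``p``."""
    arr = as_partition(p)
    _, sizes = np.unique(arr, return_counts=True)
    return entropy_from_counts(sizes, arr.size)


def joint_entropy(t: ContingencyTable) -> float:
    """Joint entropy in bits of the cell distribution of a contingency table."""
    return entropy_from_counts(t.counts, t.n_items)


def mutual_information(t: ContingencyTable) -> float:
    """Mutual information in bits: H(a) + H(z) − H(a, z)."""
    n = t.n_items
    ha = entropy_from_counts(t.row_margins, n)
    hz = entropy_from_counts(t.col_margins, n)
    return ha + hz - joint_entropy(t)


def bell_number(n: int) -> int:
    """Exact number of set partitions of ``n`` items (Bell number)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    return int(sympy.bell(n))
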