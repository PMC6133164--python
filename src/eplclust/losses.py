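"""Loss functions on pairs of partitions and the expected posterior loss.

Every loss here depends on the two partitions only through their contingency
table, and admits the decomposition

    L = f0( sum_gh f1(n_gh),  sum_g f2(n_g^a),  sum_h f3(n_h^z) )

with f1, f2, f3 evaluable per count in constant time.  That structure is what
makes single-item reallocations cheap inside the greedy optimiser: a move
touches two cells and two row margins, so each of the three sums changes by a
handful of terms.

Implemented members:

* ``B``   — Binder's loss, the number of pairwise co-clustering disagreements.
* ``VI``  — variation of information, ``2 H(a,z) − H(a) − H(z)`` (bits); a
  metric on the space of partitions.
* ``NVI`` — normalised VI, ``1 − I(a,z) / H(a,z)``, values in [0, 1].
* ``NID`` — normalised information distance, ``1 − I(a,z) / max(H(a), H(z))``.

For NVI and NID a zero denominator can only occur when both partitions have a
single group (hence are identical); the loss is defined as 0 there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .partitions import (
    ContingencyTable,
    PartitionSample,
    as_partition,
    contingency_table,
    entropy_from_counts,
    joint_entropy,
    mutual_information,
)

__all__ = [
    "LossSpec",
    "get_loss",
    "LOSS_NAMES",
    "binder_loss",
    "vi_loss",
    "nvi_loss",
    "nid_loss",
    "loss_from_table",
    "loss_via_decomposition",
    "expected_posterior_loss",
]


def _plogp(counts: np.ndarray, n_items: int) -> np.ndarray:
    """(x/N) log2(x/N) per count, with the 0 log 0 = 0 convention."""
    p = np.asarray(counts, dtype=np.float64) / n_items
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log2(p[pos])
    return out


def _square(counts: np.ndarray, n_items: int) -> np.ndarray:
    return np.asarray(counts, dtype=np.float64) ** 2


@dataclass(frozen=True)
class LossSpec:
    """A contingency-table loss in the f0/f1/f2/f3 decomposition.

    ``f1``, ``f2``, ``f3`` map arrays of counts (given the total ``N``) to
    per-count terms; ``f0`` combines the three sums (broadcasting, so it can
    be applied across many sample rows at once).
    """

    name: str
    f1: Callable[[np.ndarray, int], np.ndarray]
    f2: Callable[[np.ndarray, int], np.ndarray]
    f3: Callable[[np.ndarray, int], np.ndarray]
    f0: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]

    def count_lut(self, which: str, n_items: int) -> np.ndarray:
        """Lookup table of f{1,2,3} over integer counts 0..N (fast path).

        Padded one slot past N so vectorised "add one item" probes are safe
        even for the (masked) candidate equal to the current group.
        """
        f = {"f1": self.f1, "f2": self.f2, "f3": self.f3}[which]
        return f(np.arange(n_items + 2), n_items)


def _f0_binder(s1, s2, s3):
    return 0.5 * s2 + 0.5 * s3 - s1


def _f0_vi(s1, s2, s3):
    # sums are of (x/N)log2(x/N): H(a,z) = -s1, H(a) = -s2, H(z) = -s3
    return -2.0 * s1 + s2 + s3


def _f0_nvi(s1, s2, s3):
    haz = -np.asarray(s1, dtype=np.float64)
    i = s1 - s2 - s3  # H(a) + H(z) - H(a,z) with H = -sum
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(haz > 0, 1.0 - i / np.where(haz > 0, haz, 1.0), 0.0)
    return out


def _f0_nid(s1, s2, s3):
    ha = -np.asarray(s2, dtype=np.float64)
    hz = -np.asarray(s3, dtype=np.float64)
    haz = -np.asarray(s1, dtype=np.float64)
    hmax = np.maximum(ha, hz)
    i = ha + hz - haz
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(hmax > 0, 1.0 - i / np.where(hmax > 0, hmax, 1.0), 0.0)
    return out


_LOSSES = {
    "B": LossSpec("B", _square, _square, _square, _f0_binder),
    "VI": LossSpec("VI", _plogp, _plogp, _plogp, _f0_vi),
    "NVI": LossSpec("NVI", _plogp, _plogp, _plogp, _f0_nvi),
    "NID": LossSpec("NID", _plogp, _plogp, _plogp, _f0_nid),
}

LOSS_NAMES = tuple(_LOSSES)


def get_loss(name) -> LossSpec:
    """Look up a loss by name ("B", "VI", "NVI", "NID"); passes specs through."""
    if isinstance(name, LossSpec):
        return name
    try:
        return _LOSSES[str(name).upper()]
    except KeyError:
        raise ValueError(
            f"unknown loss {name!r}; choose one of {', '.join(_LOSSES)}"
        ) from None


# ---------------------------------------------------------------------------
# direct formulas (used as the reference route; the greedy optimiser works
# through the decomposition instead)

def binder_loss(t: ContingencyTable) -> float:
    """Binder's loss: ½Σ(n_g^a)² + ½Σ(n_h^z)² − Σ(n_gh)²."""
    c = t.counts.astype(np.float64)
    return float(
        0.5 * (t.row_margins.astype(np.float64) ** 2).sum()
        + 0.5 * (t.col_margins.astype(np.float64) ** 2).sum()
        - (c**2).sum()
    )


def vi_loss(t: ContingencyTable) -> float:
    """Variation of information in bits: 2 H(a,z) − H(a) − H(z)."""
    n = t.n_items
    ha = entropy_from_counts(t.row_margins, n)
    hz = entropy_from_counts(t.col_margins, n)
    return 2.0 * joint_entropy(t) - ha - hz


def nvi_loss(t: ContingencyTable) -> float:
    """Normalised VI: 1 − I/H(a,z); 0 when both partitions are one group."""
    haz = joint_entropy(t)
    if haz <= 0.0:
        return 0.0
    return 1.0 - mutual_information(t) / haz


def nid_loss(t: ContingencyTable) -> float:
    """Normalised information distance: 1 − I/max(H(a), H(z)); 0 when degenerate."""
    n = t.n_items
    hmax = max(
        entropy_from_counts(t.row_margins, n),
        entropy_from_counts(t.col_margins, n),
    )
    if hmax <= 0.0:
        return 0.0
    return 1.0 - mutual_information(t) / hmax


_DIRECT = {"B": binder_loss, "VI": vi_loss, "NVI": nvi_loss, "NID": nid_loss}


def loss_from_table(t: ContingencyTable, loss) -> float:
    """Evaluate a named loss on a contingency table via its direct formula."""
    spec = get_loss(loss)
    return _DIRECT[spec.name](t)


def loss_via_decomposition(t: ContingencyTable, loss) -> float:
    """Evaluate a loss through its f0/f1/f2/f3 decomposition (same value)."""
    spec = get_loss(loss)
    n = t.n_items
    s1 = spec.f1(t.counts, n).sum()
    s2 = spec.f2(t.row_margins, n).sum()
    s3 = spec.f3(t.col_margins, n).sum()
    return float(spec.f0(s1, s2, s3))


def partition_loss(a, z, loss) -> float:
    """Loss between two label vectors (convenience wrapper)."""
    return loss_from_table(contingency_table(a, z), loss)


def expected_posterior_loss(a, sample: PartitionSample, loss) -> float:
    """Weighted average loss of decision ``a`` against a partition sample.

    Returns ``(Σ_t ω_t L(a, z_t)) / Σ_t ω_t``, which for a raw (unit-weight)
    sample is the plain sample average and is numerically identical on a
    sample and its compressed form.
    """
    spec = get_loss(loss)
    a = as_partition(a)
    if a.size != sample.n_items:
        raise ValueError(
            f"decision has {a.size} items but sample has {sample.n_items}"
        )
    total = 0.0
    for t in range(sample.n_draws):
        tab = contingency_table(a, sample.labels[t])
        total += sample.weights[t] * _DIRECT[spec.name](tab)
    return total / sample.total_weight
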