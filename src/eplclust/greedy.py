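"""Greedy minimisation of the expected posterior loss over partitions.

The optimiser maintains a current decision ``a`` together with its group
sizes and the contingency table of ``a`` against every unique sample row.
Reallocating one item from group ``r`` to group ``s`` touches exactly two
group sizes and, per sample row, the two table cells in column ``v`` (the
item's label in that row), so the change in the expected loss is evaluated
in O(T̃) through the f0/f1/f2/f3 decomposition rather than by recomputing
anything from scratch.  A sweep visits every item once in random order and
applies, per item, the single best strictly-decreasing move; the run stops
when a full sweep changes nothing.  Each sweep costs O(T̃ · N · K_up).

Because the procedure is greedy it can stop in a local optimum; several
random restarts are used and the best result returned.  Starting partitions
are drawn uniformly with close to ``K_up`` groups — the sweep dynamics
readily empty groups but rarely populate new ones, so starting large gives
the optimiser room to select the number of groups downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compressor import compress_sample
from .losses import LossSpec, expected_posterior_loss, get_loss
from .partitions import PartitionSample, canonical_relabel

__all__ = ["GreedyConfig", "GreedyResult", "SweepState", "delta_epl",
           "greedy_sweep", "minimise_epl"]

# moves must decrease the objective by more than this to be accepted; guards
# against float noise re-accepting null moves and guarantees termination
_MOVE_TOL = 1e-12


@dataclass(frozen=True)
class GreedyConfig:
    """Settings for the greedy optimiser.

    ``k_up`` caps the number of groups the decision may use (default: N,
    the most permissive choice); ``restarts`` independent runs are made from
    random starting partitions and the best kept; ``max_sweeps`` is a safety
    cap on sweeps per restart (convergence normally takes far fewer).
    """

    k_up: int | None = None
    restarts: int = 16
    seed: int | None = None
    max_sweeps: int = 100


@dataclass
class GreedyResult:
    """Outcome of a greedy run: the best decision found and diagnostics."""

    partition: np.ndarray
    epl: float
    loss_name: str
    k: int
    traces: list = field(repr=False, default_factory=list)
    sweeps_per_restart: list = field(default_factory=list)
    n_restarts_hit_best: int = 0
    seed: int | None = None


class SweepState:
    """Mutable optimiser state: current decision plus cached statistics.

    Caches: group sizes ``n_a`` (length ``k_up``, empty slots allowed), the
    contingency counts of ``a`` against every unique sample row, and the
    three decomposition sums per row.  ``refresh`` recomputes the float
    caches from the integer counts, which is done at every sweep boundary to
    stop round-off drift.
    """

    def __init__(self, a, sample: PartitionSample, loss, k_up: int | None = None):
        self.spec: LossSpec = get_loss(loss)
        self.sample = sample
        n = sample.n_items
        a = np.asarray(a, dtype=np.int64)
        if a.shape != (n,):
            raise ValueError("decision length must match the sample")
        self.k_up = int(k_up) if k_up is not None else n
        if not 1 <= self.k_up <= n:
            raise ValueError("k_up must be between 1 and N")
        if a.min() < 0 or a.max() >= self.k_up:
            raise ValueError("decision labels must lie in [0, k_up)")
        self.a = a.copy()
        self.n = n
        self.weights = sample.weights
        self.w_total = float(self.weights.sum())

        # canonical 0-based sample rows and per-row number of groups
        tt = sample.n_draws
        self.z = np.empty((tt, n), dtype=np.int64)
        for t in range(tt):
            self.z[t] = canonical_relabel(sample.labels[t]) - 1
        self.kz = self.z.max(axis=1) + 1
        vmax = int(self.kz.max())

        self.lut1 = self.spec.count_lut("f1", n)
        self.lut2 = self.spec.count_lut("f2", n)
        lut3 = self.spec.count_lut("f3", n)

        self.n_a = np.bincount(self.a, minlength=self.k_up).astype(np.int64)
        self.ctab = np.zeros((tt, self.k_up, vmax), dtype=np.int64)
        t_idx = np.arange(tt)[:, None]
        np.add.at(self.ctab, (t_idx, self.a[None, :], self.z), 1)

        # s3 depends only on the sample rows, never on the decision
        self.s3 = np.array(
            [lut3[np.bincount(self.z[t], minlength=1)].sum() for t in range(tt)]
        )
        self._t_idx = np.arange(tt)
        self.s1 = np.empty(tt)
        self.s2 = 0.0
        self.psi = 0.0
        self.refresh()

    # -- cache maintenance -------------------------------------------------
    def refresh(self) -> None:
        """Recompute the float caches (s1, s2, psi) from the integer counts."""
        self.s1 = self.lut1[self.ctab].sum(axis=(1, 2))
        self.s2 = float(self.lut2[self.n_a].sum())
        self.psi = self._psi_from_sums(self.s1, self.s2)

    def _psi_from_sums(self, s1, s2) -> float:
        vals = self.spec.f0(s1, s2, self.s3)
        return float(self.weights @ vals) / self.w_total

    @property
    def n_groups(self) -> int:
        return int(np.count_nonzero(self.n_a))

    # -- move evaluation ---------------------------------------------------
    def move_deltas(self, i: int, candidates: np.ndarray) -> np.ndarray:
        """Change in EPL for moving item ``i`` to each candidate group."""
        r = int(self.a[i])
        v = self.z[:, i]
        # counts of (group, v) per sample row, shape (T, k_up)
        colv = np.take_along_axis(self.ctab, v[:, None, None], axis=2)[:, :, 0]
        cr = colv[:, r]
        rem1 = self.lut1[cr - 1] - self.lut1[cr]
        cs = colv[:, candidates]
        ds1 = rem1[:, None] + self.lut1[cs + 1] - self.lut1[cs]
        ds2 = (
            self.lut2[self.n_a[r] - 1]
            - self.lut2[self.n_a[r]]
            + self.lut2[self.n_a[candidates] + 1]
            - self.lut2[self.n_a[candidates]]
        )
        vals = self.spec.f0(
            self.s1[:, None] + ds1, self.s2 + ds2[None, :], self.s3[:, None]
        )
        dpsi = (self.weights @ vals) / self.w_total - self.psi
        dpsi[candidates == r] = 0.0  # staying put changes nothing
        return dpsi

    def apply_move(self, i: int, s: int, dpsi: float | None = None) -> None:
        """Reallocate item ``i`` to group ``s``, updating all caches in O(T)."""
        r = int(self.a[i])
        if s == r:
            return
        v = self.z[:, i]
        cr = self.ctab[self._t_idx, r, v]
        cs = self.ctab[self._t_idx, s, v]
        self.s1 += (
            self.lut1[cr - 1] - self.lut1[cr] + self.lut1[cs + 1] - self.lut1[cs]
        )
        self.ctab[self._t_idx, r, v] = cr - 1
        self.ctab[self._t_idx, s, v] = cs + 1
        self.s2 += (
            self.lut2[self.n_a[r] - 1]
            - self.lut2[self.n_a[r]]
            + self.lut2[self.n_a[s] + 1]
            - self.lut2[self.n_a[s]]
        )
        self.n_a[r] -= 1
        self.n_a[s] += 1
        self.a[i] = s
        if dpsi is not None:
            self.psi += dpsi
        else:
            self.psi = self._psi_from_sums(self.s1, self.s2)


def delta_epl(state: SweepState, i: int, r: int, s: int) -> float:
    """EPL change for reallocating item ``i`` from its group ``r`` to ``s``.

    ``r`` must be the item's current group; ``s`` may be any group slot below
    ``k_up``, including an empty one.  Cost O(T̃); agrees with recomputing
    the expected loss from scratch.
    """
    if not 0 <= i < state.n:
        raise ValueError(f"item index {i} out of range")
    if int(state.a[i]) != r:
        raise ValueError(f"item {i} is in group {int(state.a[i])}, not {r}")
    if not 0 <= s < state.k_up:
        raise ValueError(f"target group {s} outside [0, k_up)")
    return float(state.move_deltas(i, np.array([s]))[0])


def _candidate_groups(state: SweepState) -> np.ndarray:
    """Nonempty groups plus (at most) one empty slot as reallocation targets."""
    nonempty = np.flatnonzero(state.n_a > 0)
    if nonempty.size < state.k_up:
        first_empty = int(np.flatnonzero(state.n_a == 0)[0])
        return np.append(nonempty, first_empty)
    return nonempty


def greedy_sweep(state: SweepState, rng: np.random.Generator) -> bool:
    """One pass over all items in random order; returns whether any item moved.

    For each item every nonempty group plus one empty group (all empty slots
    being exchangeable) is tried, and the move with the largest strict
    decrease in EPL is applied; ties with the current allocation keep it.
    """
    changed = False
    for i in rng.permutation(state.n):
        candidates = _candidate_groups(state)
        dpsi = state.move_deltas(int(i), candidates)
        j = int(np.argmin(dpsi))
        if dpsi[j] < -_MOVE_TOL:
            state.apply_move(int(i), int(candidates[j]), float(dpsi[j]))
            changed = True
    return changed


def minimise_epl(sample: PartitionSample, loss, config: GreedyConfig | None = None,
                 ) -> GreedyResult:
    """Estimate the Bayes-action partition minimising the expected loss.

    The sample is compressed to unique rows first.  Each restart draws a
    uniformly random start over ``k_up`` groups, sweeps to convergence and
    records its EPL trace; the best decision across restarts is returned in
    canonical form.  Fully reproducible given ``config.seed``.
    """
    if config is None:
        config = GreedyConfig()
    spec = get_loss(loss)
    comp = compress_sample(sample)
    n = comp.n_items
    k_up = config.k_up if config.k_up is not None else n
    if not 1 <= k_up <= n:
        raise ValueError("k_up must be between 1 and N")
    if config.restarts < 1:
        raise ValueError("restarts must be positive")

    streams = np.random.SeedSequence(config.seed).spawn(config.restarts)
    best_psi = np.inf
    best_a = None
    traces: list[np.ndarray] = []
    sweeps_per_restart: list[int] = []
    finals: list[float] = []

    for ss in streams:
        rng = np.random.default_rng(ss)
        a0 = rng.integers(0, k_up, size=n)
        state = SweepState(a0, comp, spec, k_up=k_up)
        trace = [state.psi]
        for _ in range(config.max_sweeps):
            state.refresh()
            changed = greedy_sweep(state, rng)
            trace.append(state.psi)
            if not changed:
                break
        state.refresh()
        traces.append(np.asarray(trace))
        sweeps_per_restart.append(len(trace) - 1)
        finals.append(state.psi)
        if state.psi < best_psi:
            best_psi = state.psi
            best_a = state.a.copy()

    best_part = canonical_relabel(best_a + 1)
    # report the EPL of the returned partition, recomputed directly
    best_psi = expected_posterior_loss(best_part, comp, spec)
    tol = 1e-9 * max(1.0, abs(best_psi))
    hits = int(sum(f <= best_psi + tol for f in finals))
    return GreedyResult(
        partition=best_part,
        epl=best_psi,
        loss_name=spec.name,
        k=int(best_part.max()),
        traces=traces,
        sweeps_per_restart=sweeps_per_restart,
        n_restarts_hit_best=hits,
        seed=config.seed,
    )
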