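"""Greedy EPL minimisation: incremental updates, sweeps, restarts, oracle checks."""

import numpy as np
import pytest

import eplclust as ec
from conftest import random_partition, random_sample


def make_state(rng, n=6, t=12, loss="VI", k_up=None):
    s = ec.compress_sample(random_sample(rng, n, t, 3))
    k_up = k_up or n
    a = rng.integers(0, k_up, size=n)
    return ec.SweepState(a, s, loss, k_up=k_up), s


@pytest.mark.parametrize("loss", ec.LOSS_NAMES)
def test_delta_epl_matches_full_recomputation(loss, rng):
    for _ in range(60):
        n = int(rng.integers(3, 9))
        state, s = make_state(rng, n=n, t=int(rng.integers(3, 20)), loss=loss)
        i = int(rng.integers(n))
        r = int(state.a[i])
        target = int(rng.integers(state.k_up))
        d = ec.delta_epl(state, i, r, target)
        a_new = state.a.copy()
        a_new[i] = target
        psi_old = ec.expected_posterior_loss(state.a + 1, s, loss)
        psi_new = ec.expected_posterior_loss(a_new + 1, s, loss)
        assert d == pytest.approx(psi_new - psi_old, abs=1e-9)


def test_delta_epl_noop_and_errors(rng):
    state, _ = make_state(rng)
    i = 2
    r = int(state.a[i])
    assert ec.delta_epl(state, i, r, r) == 0.0
    with pytest.raises(ValueError):
        ec.delta_epl(state, i, r + 1, 0)  # r is not item i's group
    with pytest.raises(ValueError):
        ec.delta_epl(state, 99, 0, 0)


def test_delta_epl_positive_off_concentrated_truth(rng):
    # sample = copies of a: any move away from a strictly raises VI EPL
    z = np.array([1, 1, 2, 2, 3])
    s = ec.PartitionSample(np.tile(z, (6, 1)))
    state = ec.SweepState(z - 1, ec.compress_sample(s), "VI", k_up=5)
    for i in range(5):
        r = int(state.a[i])
        for target in range(5):
            if target == r:
                continue
            moved = state.a.copy()
            moved[i] = target
            if ec.partitions_equivalent(moved + 1, z):
                # e.g. a singleton hopping to an empty slot: same partition
                assert ec.delta_epl(state, i, r, target) == pytest.approx(0, abs=1e-12)
            else:
                assert ec.delta_epl(state, i, r, target) > 0


def test_apply_move_keeps_caches_consistent(rng):
    for loss in ec.LOSS_NAMES:
        state, s = make_state(rng, n=7, t=15, loss=loss)
        rng2 = np.random.default_rng(1)
        for _ in range(12):
            i = int(rng2.integers(7))
            target = int(rng2.integers(state.k_up))
            state.apply_move(i, target)
            # cached tables equal tables rebuilt from scratch
            fresh = ec.SweepState(state.a, s, loss, k_up=state.k_up)
            assert np.array_equal(state.ctab, fresh.ctab)
            assert np.array_equal(state.n_a, fresh.n_a)
            assert state.psi == pytest.approx(fresh.psi, abs=1e-9)


def test_sweep_at_local_optimum_reports_no_change(rng):
    z = np.array([1, 1, 2, 2])
    s = ec.compress_sample(ec.PartitionSample(np.tile(z, (5, 1))))
    state = ec.SweepState(z - 1, s, "VI", k_up=4)
    psi_before = state.psi
    assert psi_before == pytest.approx(0.0, abs=1e-12)
    changed = ec.greedy_sweep(state, np.random.default_rng(0))
    assert not changed
    assert np.array_equal(state.a, z - 1)


def test_sweep_single_item_no_move(rng):
    s = ec.PartitionSample(np.array([[1], [1]]))
    state = ec.SweepState(np.array([0]), ec.compress_sample(s), "VI", k_up=1)
    assert not ec.greedy_sweep(state, np.random.default_rng(0))


def test_sweep_improves_improvable_state(rng):
    # truth-concentrated sample; start one item off truth: sweep must fix it
    z = np.array([1, 1, 2, 2])
    s = ec.compress_sample(ec.PartitionSample(np.tile(z, (8, 1))))
    a0 = np.array([0, 1, 1, 1])
    state = ec.SweepState(a0, s, "VI", k_up=4)
    psi0 = state.psi
    changed = ec.greedy_sweep(state, np.random.default_rng(3))
    assert changed and state.psi < psi0
    # enumeration oracle: no single move from the reached state does better
    best_single = min(
        ec.delta_epl(state, i, int(state.a[i]), t)
        for i in range(4)
        for t in range(4)
    )
    assert best_single >= -1e-12


@pytest.mark.parametrize("loss", ec.LOSS_NAMES)
def test_minimise_on_concentrated_sample_recovers_truth(loss, rng):
    z = random_partition(rng, 10, 3)
    s = ec.PartitionSample(np.tile(z, (20, 1)))
    res = ec.minimise_epl(s, loss, ec.GreedyConfig(restarts=4, seed=5))
    assert ec.partitions_equivalent(res.partition, z)
    assert res.epl == pytest.approx(0.0, abs=1e-12)
    assert res.k == len(set(z.tolist()))


@pytest.mark.parametrize("loss", ec.LOSS_NAMES)
def test_minimise_matches_exhaustive_oracle_small(loss, rng):
    # N=6: all 203 set partitions enumerated as the ground truth
    for _ in range(5):
        truth = random_partition(rng, 6, 3)
        s = ec.perturb_partition_sample(truth, 20, 0.25, k_up=6,
                                        seed=int(rng.integers(2**31)))
        _, opt = ec.exhaustive_minimise(s, loss)
        res = ec.minimise_epl(
            s, loss, ec.GreedyConfig(k_up=6, restarts=20, seed=int(rng.integers(2**31)))
        )
        assert res.epl >= opt - 1e-9
        assert res.epl == pytest.approx(opt, abs=1e-9)


def test_trace_non_increasing_and_terminates(rng):
    s = random_sample(rng, 12, 40, 4)
    res = ec.minimise_epl(s, "VI", ec.GreedyConfig(restarts=6, seed=9))
    for trace in res.traces:
        assert np.all(np.diff(trace) <= 1e-12)
    assert all(sw <= 100 for sw in res.sweeps_per_restart)
    assert 1 <= res.n_restarts_hit_best <= 6


def test_result_invariant_to_row_relabelling_and_duplication(rng):
    truth = random_partition(rng, 15, 3)
    s = ec.perturb_partition_sample(truth, 40, 0.1, seed=11)
    cfg = ec.GreedyConfig(k_up=6, restarts=4, seed=21)
    base = ec.minimise_epl(s, "VI", cfg)

    # relabel every row randomly: same decision up to equivalence
    relabelled = s.labels.copy()
    for t in range(s.n_draws):
        perm = rng.permutation(int(relabelled[t].max())) + 1
        relabelled[t] = perm[relabelled[t] - 1]
    res_rel = ec.minimise_epl(ec.PartitionSample(relabelled), "VI", cfg)
    assert ec.partitions_equivalent(res_rel.partition, base.partition)
    assert res_rel.epl == pytest.approx(base.epl, abs=1e-9)

    # doubling every row leaves the optimum and its EPL unchanged
    doubled = ec.PartitionSample(np.vstack([s.labels, s.labels]))
    res_dbl = ec.minimise_epl(doubled, "VI", cfg)
    assert ec.partitions_equivalent(res_dbl.partition, base.partition)
    assert res_dbl.epl == pytest.approx(base.epl, abs=1e-9)


def test_seed_reproducibility(rng):
    s = random_sample(rng, 10, 25, 4)
    cfg = ec.GreedyConfig(restarts=3, seed=123)
    r1 = ec.minimise_epl(s, "VI", cfg)
    r2 = ec.minimise_epl(s, "VI", cfg)
    assert np.array_equal(r1.partition, r2.partition)
    assert r1.epl == r2.epl


def test_config_validation(rng):
    s = random_sample(rng, 5, 5)
    with pytest.raises(ValueError):
        ec.minimise_epl(s, "VI", ec.GreedyConfig(k_up=0))
    with pytest.raises(ValueError):
        ec.minimise_epl(s, "VI", ec.GreedyConfig(k_up=9))
    with pytest.raises(ValueError):
        ec.minimise_epl(s, "VI", ec.GreedyConfig(restarts=0))
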