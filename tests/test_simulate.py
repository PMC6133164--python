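"""Synthetic generators and the demo DP-mixture collapsed Gibbs sampler."""

import collections

import numpy as np
import pytest

import eplclust as ec


def test_example_presets():
    c1 = ec.example1_config(n=100)
    assert np.allclose(c1.weights, 0.25)
    assert c1.means.tolist() == [[1, 1], [-1, 1], [-1, -1], [1, -1]]
    assert np.allclose(c1.covariances[0], np.eye(2))
    assert np.allclose(c1.covariances[1], 0.5 * np.eye(2))
    assert np.allclose(c1.covariances[3], 1.5 * np.eye(2))

    c2 = ec.example2_config(sigma=0.9)
    assert all(np.allclose(c2.covariances[g], 0.9 * np.eye(2)) for g in range(4))
    with pytest.raises(ValueError):
        ec.example2_config(sigma=0.0)


def test_mixture_config_validation():
    with pytest.raises(ValueError):
        ec.MixtureSimConfig(
            weights=[0.5, 0.4],  # does not sum to 1
            means=np.zeros((2, 2)),
            covariances=np.stack([np.eye(2)] * 2),
        )
    bad_cov = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
    with pytest.raises(ValueError):
        ec.MixtureSimConfig(
            weights=[1.0], means=np.zeros((1, 2)), covariances=bad_cov[None]
        )


def test_generate_mixture_frequencies_and_means():
    cfg = ec.example1_config(n=100_000, seed=4)
    data = ec.generate_mixture_data(cfg)
    freq = np.bincount(data.z - 1, minlength=4) / cfg.n
    # binomial MC error ~ sqrt(.25*.75/1e5) ~ 0.0014
    assert np.allclose(freq, 0.25, atol=0.01)
    for g in range(4):
        within = data.y[data.z == g + 1]
        assert np.allclose(within.mean(axis=0), cfg.means[g], atol=0.05)


def test_generate_mixture_degenerate_cases():
    cfg = ec.example1_config(n=0, seed=1)
    data = ec.generate_mixture_data(cfg)
    assert data.y.shape == (0, 2) and data.z.shape == (0,)

    tight = ec.MixtureSimConfig(
        weights=[0.5, 0.5],
        means=np.array([[2.0, 0.0], [-2.0, 0.0]]),
        covariances=np.stack([np.eye(2) * 1e-12] * 2),
        n=50,
        seed=2,
    )
    data = ec.generate_mixture_data(tight)
    assert np.all(
        np.abs(data.y - tight.means[data.z - 1]) < 1e-4
    )


def test_perturb_rate_zero_is_fixed_point():
    truth = np.repeat([1, 2, 3], 5)
    s = ec.perturb_partition_sample(truth, 25, 0.0, seed=7)
    for t in range(25):
        assert ec.partitions_equivalent(s.labels[t], truth)
    c = ec.compress_sample(s)
    assert c.n_draws == 1 and c.weights[0] == 25


def test_perturb_validation_and_noise_level():
    truth = np.repeat([1, 2], 50)
    with pytest.raises(ValueError):
        ec.perturb_partition_sample(truth, 10, 1.5)
    with pytest.raises(ValueError):
        ec.perturb_partition_sample(truth, 10, 0.1, k_up=1)
    s = ec.perturb_partition_sample(truth, 200, 0.2, k_up=4, seed=3)
    # expected fraction of items moved off truth: rate * (1 - 1/k_up) = 0.15
    mism = np.mean([
        1 - (ec.contingency_table(truth, s.labels[t]).counts.max(axis=1).sum() / 100)
        for t in range(200)
    ])
    assert 0.10 < mism < 0.20


def test_crp_prior_mean_number_of_groups():
    # likelihood off: the chain targets the CRP prior; E[K] = sum alpha/(alpha+i-1)
    n, alpha = 5, 1.0
    cfg = ec.DPGMMConfig(alpha=alpha, burn_in=500, thin=1, n_draws=20_000,
                         seed=13, use_likelihood=False)
    y = np.random.default_rng(0).standard_normal((n, 2))
    s = ec.dpgmm_collapsed_gibbs(y, cfg)
    ks = s.labels.max(axis=1)
    expected = sum(alpha / (alpha + i) for i in range(n))
    # batch-means standard error to respect autocorrelation
    batches = ks.reshape(100, -1).mean(axis=1)
    se = batches.std(ddof=1) / np.sqrt(len(batches))
    assert abs(ks.mean() - expected) < 3 * se + 1e-3


def test_tiny_alpha_concentrates_on_one_group():
    y = np.random.default_rng(5).standard_normal((40, 2))
    cfg = ec.DPGMMConfig(alpha=1e-8, burn_in=300, thin=2, n_draws=200, seed=17)
    s = ec.dpgmm_collapsed_gibbs(y, cfg)
    ks = s.labels.max(axis=1)
    assert np.mean(ks == 1) > 0.95


def test_dpgmm_separated_data_recovered():
    cfg = ec.MixtureSimConfig(
        weights=np.full(3, 1 / 3),
        means=np.array([[6.0, 0.0], [-6.0, 6.0], [-6.0, -6.0]]),
        covariances=np.stack([0.5 * np.eye(2)] * 3),
        n=60,
        seed=8,
    )
    data = ec.generate_mixture_data(cfg)
    s = ec.dpgmm_collapsed_gibbs(
        data, ec.DPGMMConfig(burn_in=500, thin=2, n_draws=300, seed=19)
    )
    res = ec.minimise_epl(s, "VI", ec.GreedyConfig(k_up=10, restarts=4, seed=23))
    assert ec.partitions_equivalent(res.partition, data.z)


def test_dpgmm_example1_posterior_mode_and_vi_distance():
    # overlapping four-component data: posterior-mode K lands near the truth
    # and the VI summary is within a few bits of the true allocation
    data = ec.generate_mixture_data(ec.example1_config(200, seed=100))
    post = ec.dpgmm_collapsed_gibbs(
        data, ec.DPGMMConfig(burn_in=2000, thin=5, n_draws=1000, seed=200)
    )
    ks = post.labels.max(axis=1)
    mode_k = collections.Counter(ks.tolist()).most_common(1)[0][0]
    assert mode_k in {3, 4, 5}
    res = ec.minimise_epl(post, "VI", ec.GreedyConfig(k_up=20, restarts=4, seed=300))
    assert ec.partition_loss(res.partition, data.z, "VI") < 3.0


def test_dpgmm_input_validation():
    with pytest.raises(ValueError):
        ec.dpgmm_collapsed_gibbs(np.zeros((1, 2)), ec.DPGMMConfig())
    with pytest.raises(ValueError):
        ec.dpgmm_collapsed_gibbs(np.zeros((5, 3)), ec.DPGMMConfig())
    with pytest.raises(ValueError):
        ec.DPGMMConfig(alpha=0.0)
    with pytest.raises(ValueError):
        ec.DPGMMConfig(nu=1.0)


def test_dpgmm_invariant_to_seeded_rerun():
    y = np.random.default_rng(9).standard_normal((20, 2))
    cfg = ec.DPGMMConfig(burn_in=100, thin=1, n_draws=50, seed=31)
    s1 = ec.dpgmm_collapsed_gibbs(y, cfg)
    s2 = ec.dpgmm_collapsed_gibbs(y, cfg)
    assert np.array_equal(s1.labels, s2.labels)
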