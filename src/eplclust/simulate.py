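"""Synthetic fixtures: Gaussian mixtures, noisy partition samples, and a
demo collapsed Gibbs sampler for a Dirichlet-process Gaussian mixture.

These generators let the whole pipeline — sample, compress, summarise — run
end to end without any external data.  ``generate_mixture_data`` draws from
a bivariate Gaussian mixture via its latent-allocation representation;
``perturb_partition_sample`` fabricates a partition sample concentrated near
a known truth with reallocation noise and label switching, mimicking
well-mixed MCMC output; ``dpgmm_collapsed_gibbs`` is a genuine (if modestly
configured) collapsed Gibbs sampler over allocations for an infinite
Gaussian mixture with a conjugate normal–inverse-Wishart base measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .partitions import PartitionSample, as_partition, canonical_relabel

__all__ = [
    "MixtureSimConfig",
    "MixtureData",
    "DPGMMConfig",
    "example1_config",
    "example2_config",
    "generate_mixture_data",
    "perturb_partition_sample",
    "dpgmm_collapsed_gibbs",
]


@dataclass(frozen=True)
class MixtureSimConfig:
    """A bivariate Gaussian mixture: weights, component means and covariances."""

    weights: np.ndarray
    means: np.ndarray  # (K, 2)
    covariances: np.ndarray  # (K, 2, 2), each symmetric positive definite
    n: int = 100
    seed: int | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        mu = np.asarray(self.means, dtype=np.float64)
        cov = np.asarray(self.covariances, dtype=np.float64)
        if w.ndim != 1 or w.size == 0 or np.any(w <= 0):
            raise ValueError("mixture weights must be positive")
        if not math.isclose(w.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        k = w.size
        if mu.shape != (k, 2):
            raise ValueError("means must have shape (K, 2)")
        if cov.shape != (k, 2, 2):
            raise ValueError("covariances must have shape (K, 2, 2)")
        for g in range(k):
            if not np.allclose(cov[g], cov[g].T):
                raise ValueError(f"covariance {g} is not symmetric")
            if np.linalg.eigvalsh(cov[g])[0] <= 0:
                raise ValueError(f"covariance {g} is not positive definite")
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "covariances", cov)


@dataclass(frozen=True)
class MixtureData:
    """Observations plus the true allocations that generated them."""

    y: np.ndarray  # (N, 2)
    z: np.ndarray  # (N,), 1-based component labels


def example1_config(n: int = 400, seed: int | None = None) -> MixtureSimConfig:
    """Four equally weighted Gaussians at (±1, ±1) with unequal spreads.

    Weights 1/4 each; means (1,1), (−1,1), (−1,−1), (1,−1); covariances
    I, 0.5·I, I and 1.5·I.  The components overlap substantially, so the
    clustering is identifiable but genuinely uncertain.
    """
    eye = np.eye(2)
    return MixtureSimConfig(
        weights=np.full(4, 0.25),
        means=np.array([[1.0, 1.0], [-1.0, 1.0], [-1.0, -1.0], [1.0, -1.0]]),
        covariances=np.stack([eye, 0.5 * eye, eye, 1.5 * eye]),
        n=n,
        seed=seed,
    )


def example2_config(sigma: float, n: int = 100, seed: int | None = None
                    ) -> MixtureSimConfig:
    """Same four components as ``example1_config`` but isotropic σ·I spreads.

    Larger ``sigma`` makes the components overlap more and the clustering
    task harder.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    eye = np.eye(2)
    return MixtureSimConfig(
        weights=np.full(4, 0.25),
        means=np.array([[1.0, 1.0], [-1.0, 1.0], [-1.0, -1.0], [1.0, -1.0]]),
        covariances=np.stack([sigma * eye] * 4),
        n=n,
        seed=seed,
    )


def generate_mixture_data(config: MixtureSimConfig) -> MixtureData:
    """Draw allocations from the mixture weights, then observations from the
    allocated Gaussian components."""
    rng = np.random.default_rng(config.seed)
    k = config.weights.size
    z = rng.choice(k, size=config.n, p=config.weights)
    y = np.empty((config.n, 2))
    chols = [np.linalg.cholesky(config.covariances[g]) for g in range(k)]
    for g in range(k):
        idx = np.flatnonzero(z == g)
        if idx.size:
            y[idx] = config.means[g] + rng.standard_normal((idx.size, 2)) @ chols[g].T
    return MixtureData(y=y, z=z + 1)


def perturb_partition_sample(truth, n_draws: int, rate: float,
                             k_up: int | None = None,
                             seed: int | None = None) -> PartitionSample:
    """A partition sample concentrated at ``truth`` with reallocation noise.

    Each row starts from the true partition; every item is independently
    reassigned to a uniform label in {1..k_up} with probability ``rate``, and
    a uniformly random label permutation is then applied to the whole row to
    emulate the label switching of mixture MCMC output.
    """
    truth = canonical_relabel(as_partition(truth))
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    if k_up is None:
        k_up = int(truth.max())
    if k_up < int(truth.max()):
        raise ValueError("k_up must be at least the number of groups in truth")
    rng = np.random.default_rng(seed)
    n = truth.size
    rows = np.tile(truth, (n_draws, 1))
    mask = rng.random((n_draws, n)) < rate
    rows[mask] = rng.integers(1, k_up + 1, size=int(mask.sum()))
    for t in range(n_draws):
        perm = rng.permutation(k_up) + 1
        rows[t] = perm[rows[t] - 1]
    return PartitionSample(rows)


@dataclass(frozen=True)
class DPGMMConfig:
    """Demo Dirichlet-process Gaussian-mixture sampler settings.

    The base measure is conjugate: Σ_g ~ InverseWishart(ν, uνI) and
    μ_g | Σ_g ~ N(0, Σ_g / a).  The concentration α and the hyperparameters
    a, ν, u are held fixed (no hyperpriors) — this sampler exists to feed the
    summariser with realistic posterior partition samples, not to be a
    production mixture engine.  ``use_likelihood=False`` switches the data
    term off so the chain targets the CRP prior (used for calibration
    checks).
    """

    alpha: float = 1.0
    a: float = 0.1
    nu: float = 4.0
    u: float = 0.5
    burn_in: int = 2000
    thin: int = 5
    n_draws: int = 1000
    seed: int | None = None
    use_likelihood: bool = True

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.nu <= 1:  # need nu > d - 1 = 1 for a proper inverse Wishart
            raise ValueError("nu must exceed 1 for 2-D data")
        if self.a <= 0 or self.u <= 0:
            raise ValueError("a and u must be positive")
        if self.burn_in < 0 or self.thin < 1 or self.n_draws < 1:
            raise ValueError("invalid chain length settings")


@njit(cache=True)
def _log_predictive(x0, x1, cnt, sx0, sx1, sxx00, sxx01, sxx11,
                    kappa0, nu0, lam0):
    """Log posterior-predictive density of (x0, x1) for one group.

    Closed-form bivariate Student-t under the conjugate normal–inverse-
    Wishart posterior with the group's sufficient statistics.
    """
    kn = kappa0 + cnt
    nun = nu0 + cnt
    mu0 = sx0 / kn
    mu1 = sx1 / kn
    # Lambda_n = lam0*I + sum(xx^T) - (sum x)(sum x)^T / kn
    l00 = lam0 + sxx00 - sx0 * sx0 / kn
    l01 = sxx01 - sx0 * sx1 / kn
    l11 = lam0 + sxx11 - sx1 * sx1 / kn
    df = nun - 1.0  # nu_n - d + 1 with d = 2
    c = (kn + 1.0) / (kn * df)
    s00 = l00 * c
    s01 = l01 * c
    s11 = l11 * c
    det = s00 * s11 - s01 * s01
    d0 = x0 - mu0
    d1 = x1 - mu1
    m = (s11 * d0 * d0 - 2.0 * s01 * d0 * d1 + s00 * d1 * d1) / det
    return (
        math.lgamma(0.5 * (df + 2.0))
        - math.lgamma(0.5 * df)
        - math.log(df * math.pi)
        - 0.5 * math.log(det)
        - 0.5 * (df + 2.0) * math.log1p(m / df)
    )


@njit(cache=True)
def _gibbs_chain(y, alpha, kappa0, nu0, lam0, burn_in, thin, n_draws, seed,
                 use_likelihood):
    np.random.seed(seed)
    n = y.shape[0]
    cnt = np.zeros(n, dtype=np.int64)
    sx = np.zeros((n, 2))
    sxx = np.zeros((n, 3))  # packed symmetric: xx, xy, yy
    z = np.zeros(n, dtype=np.int64)
    # start with everything in one group
    k = 1
    cnt[0] = n
    for i in range(n):
        sx[0, 0] += y[i, 0]
        sx[0, 1] += y[i, 1]
        sxx[0, 0] += y[i, 0] * y[i, 0]
        sxx[0, 1] += y[i, 0] * y[i, 1]
        sxx[0, 2] += y[i, 1] * y[i, 1]

    out = np.zeros((n_draws, n), dtype=np.int64)
    logw = np.zeros(n + 1)
    total_sweeps = burn_in + thin * n_draws
    kept = 0
    for sweep in range(total_sweeps):
        for i in range(n):
            g = z[i]
            x0 = y[i, 0]
            x1 = y[i, 1]
            # remove item i from its group
            cnt[g] -= 1
            sx[g, 0] -= x0
            sx[g, 1] -= x1
            sxx[g, 0] -= x0 * x0
            sxx[g, 1] -= x0 * x1
            sxx[g, 2] -= x1 * x1
            if cnt[g] == 0:
                k -= 1
                if g != k:  # move last group into the emptied slot
                    cnt[g] = cnt[k]
                    sx[g, 0] = sx[k, 0]
                    sx[g, 1] = sx[k, 1]
                    sxx[g, 0] = sxx[k, 0]
                    sxx[g, 1] = sxx[k, 1]
                    sxx[g, 2] = sxx[k, 2]
                    for j in range(n):
                        if z[j] == k:
                            z[j] = g
                cnt[k] = 0
                sx[k, 0] = 0.0
                sx[k, 1] = 0.0
                sxx[k, 0] = 0.0
                sxx[k, 1] = 0.0
                sxx[k, 2] = 0.0
            # CRP weights times posterior predictive
            for h in range(k):
                logw[h] = math.log(cnt[h])
                if use_likelihood:
                    logw[h] += _log_predictive(
                        x0, x1, cnt[h], sx[h, 0], sx[h, 1],
                        sxx[h, 0], sxx[h, 1], sxx[h, 2],
                        kappa0, nu0, lam0,
                    )
            logw[k] = math.log(alpha)
            if use_likelihood:
                logw[k] += _log_predictive(
                    x0, x1, 0, 0.0, 0.0, 0.0, 0.0, 0.0, kappa0, nu0, lam0
                )
            # sample the new allocation
            mx = logw[0]
            for h in range(1, k + 1):
                if logw[h] > mx:
                    mx = logw[h]
            tot = 0.0
            for h in range(k + 1):
                logw[h] = math.exp(logw[h] - mx)
                tot += logw[h]
            r = np.random.random() * tot
            acc = 0.0
            gnew = k
            for h in range(k + 1):
                acc += logw[h]
                if r <= acc:
                    gnew = h
                    break
            if gnew == k:
                k += 1
            z[i] = gnew
            cnt[gnew] += 1
            sx[gnew, 0] += x0
            sx[gnew, 1] += x1
            sxx[gnew, 0] += x0 * x0
            sxx[gnew, 1] += x0 * x1
            sxx[gnew, 2] += x1 * x1
        if sweep >= burn_in and (sweep - burn_in) % thin == thin - 1:
            if kept < n_draws:
                for j in range(n):
                    out[kept, j] = z[j] + 1
                kept += 1
    return out


def dpgmm_collapsed_gibbs(data, config: DPGMMConfig | None = None
                          ) -> PartitionSample:
    """Collapsed Gibbs sampling of allocations for a DP Gaussian mixture.

    Accepts a ``MixtureData`` or a raw (N, 2) observation array.  One item at
    a time is removed from its group and reassigned to an existing group with
    probability proportional to the group size times the group's posterior-
    predictive density at the item (a bivariate Student-t under the conjugate
    base measure), or to a new group with probability proportional to α times
    the prior predictive.  Post-burn-in, every ``thin``-th sweep's allocation
    vector is emitted.
    """
    if config is None:
        config = DPGMMConfig()
    y = data.y if isinstance(data, MixtureData) else np.asarray(data, dtype=np.float64)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("observations must be an (N, 2) array")
    if y.shape[0] < 2:
        raise ValueError("need at least two observations")
    seed = config.seed if config.seed is not None else 0
    draws = _gibbs_chain(
        np.ascontiguousarray(y, dtype=np.float64),
        float(config.alpha),
        float(config.a),
        float(config.nu),
        float(config.u * config.nu),  # inverse-Wishart scale matrix uνI
        int(config.burn_in),
        int(config.thin),
        int(config.n_draws),
        int(seed) % (2**32),
        config.use_likelihood,
    )
    return PartitionSample(draws)
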