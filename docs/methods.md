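# Methods

## Decision-theoretic summary of a partition sample

The object being estimated is a partition of `N` items, represented as a
label vector; two vectors related by a label permutation are the same
partition (`≡`). Given posterior draws `z⁽¹⁾ … z⁽ᵀ⁾` and a loss `L`, the
point estimate is the partition minimising the estimated expected posterior
loss `ψ(a) = (1/T) Σₜ L(a, z⁽ᵗ⁾)`. Nothing about the model that produced
the draws enters the computation — only the label matrix — so the same
machinery serves mixtures, block models or cluster-ensemble problems.

All losses here are functions of the contingency table between the decision
and a draw, written in the decomposed form

    L = f0( Σ_gh f1(n_gh), Σ_g f2(n_g^a), Σ_h f3(n_h^z) ),

with `f1, f2, f3` evaluable per count in constant time. For Binder's loss
the component functions are squares; for the information family they are
`x ↦ (x/N) log₂(x/N)` with the `0 log 0 = 0` convention. Logarithms are
base 2 throughout, so VI and entropies are reported in bits; Binder's loss
is kept unscaled (pair counts), so its magnitude grows like `N²`.

Conventions chosen where definitions degenerate:

* NVI and NID are defined as 0 when their denominator is 0, which happens
  only when both partitions are the single-group partition and hence equal;
  this preserves "loss 0 iff equivalent".
* The weighted EPL over a compressed sample is normalised by the total
  weight `Σω` (equal to `T` for a raw sample), so compression never changes
  the value of `ψ`, not merely its argmin.

## Sample compression and the mode

Every row is first canonicalised (groups relabelled by order of first
appearance: the first item gets label 1, and so on). Equivalent rows then
become identical label sequences, and a lexicographic sort-and-count yields
unique rows with multiplicities; row identity is decided by comparing the
canonical sequences directly, which carries the same ordering semantics as
encoding each row as a base-`K` integer without any big-integer arithmetic.
Compression costs `O(NT log T)` and is idempotent. The heaviest unique row
is the sample mode — the exact minimiser of the estimated 0–1 loss over the
sample's support, and the closest available proxy for a MAP estimate when
the summariser sees only the draws, never their posterior densities. Ties
are broken toward the lexicographically smallest canonical row for
determinism.

## The greedy optimiser

State: the current decision `a` (stored over `K_up` label slots, empty slots
permitted), its group sizes, the contingency table of `a` against every
unique sample row, and the three decomposition sums per row. Moving item `i`
from group `r` to `s` changes two group sizes and, in each row's table, the
two cells in column `v = z̃ᵢ⁽ᵗ⁾`; the resulting `Δψ` is evaluated in `O(T̃)`
through `f0`. A sweep visits all items in a freshly shuffled order and
applies, per item, the best move among all nonempty groups plus one empty
slot (empty slots are exchangeable, so offering one loses nothing); only
strictly decreasing moves are accepted — a tied best move keeps the current
allocation — which guarantees termination. The run stops when a sweep makes
no move (with a safety cap of 100 sweeps). No post-convergence merge step is
performed.

Numerical choices:

* Accepted moves update `ψ` incrementally; the float caches are recomputed
  from the integer contingency counts at every sweep boundary, so round-off
  cannot accumulate across sweeps. A move must improve `ψ` by more than
  1e−12 to be accepted.
* Restarts draw the starting partition uniformly over `{1..K_up}` labels
  per item, giving close to `K_up` starting groups; the sweep dynamics
  readily empty groups but rarely populate new ones, so starting large is
  what lets the optimiser choose `K` downward freely. `K_up` defaults to
  `N`, the most permissive setting.
* Each restart uses an independent RNG substream spawned from the run seed,
  so results depend only on the seed and not on scheduling.
* The returned EPL is recomputed from the final partition by the direct
  (non-incremental) formulas as a last consistency step.

On small instances the greedy result is validated against exhaustive
enumeration of all set partitions (Bell(N) candidates, generated through
`sympy`'s set-partition iterator, with losses evaluated by their direct
formulas — a route fully disjoint from the incremental machinery). The
package refuses exhaustive enumeration beyond `N = 12`.

## Posterior similarity matrix

`b_ij` is the weighted co-clustering frequency across the sample. The
pairwise objective `Σ_{i<j} 1{a_i=a_j}(1 − 2 b_ij)` equals the Binder EPL up
to an additive constant independent of `a` (the expected number of
co-clustered pairs per draw), so both rank decisions identically; the test
suite checks the offset's variance over random decisions rather than
trusting the algebra. This equivalence is specific to Binder's loss and is
used as a cross-check, not as the optimisation route.

## Synthetic data

`perturb_partition_sample` emulates the output of a well-mixed sampler whose
posterior concentrates near a known truth: per draw, each item is
independently reassigned uniformly over `{1..K_up}` with probability `rate`,
and a random label permutation is applied to the whole draw to reproduce
label switching. It does **not** emulate MCMC autocorrelation, multimodal
posteriors, or structured uncertainty (items near cluster boundaries being
systematically more volatile); recovery results on it speak to the
optimiser's behaviour under idealised concentrated posteriors, not to any
real sampler's output. The recovery experiments use `rate = 0.1`,
`T = 500`, `N = 100` with a 4-group truth — noise mild enough that the
truth remains the clear Bayes action, which is exactly what makes exact
recovery a meaningful check.

`generate_mixture_data` draws from a bivariate Gaussian mixture through its
latent-allocation representation. Two presets ship: four equally weighted
components at means `(±1, ±1)` with covariances `I, 0.5·I, I, 1.5·I`
(`example1_config`), and the same means with a common isotropic `σ·I`
covariance (`example2_config`). Both presets have strongly overlapping
components by design: allocation uncertainty is what makes summarising the
posterior nontrivial. A consequence worth stating plainly: with this much
overlap even the Bayes-optimal classifier that knows the true parameters
misallocates a substantial fraction of points, so no summary of any
posterior sample can agree closely with the generating allocation — pipeline
checks on these presets are therefore qualitative (plausible number of
groups, VI distance to truth within a few bits) rather than
exact-recovery tests.

`dpgmm_collapsed_gibbs` is a demonstration sampler, present so the package
exercises a genuine allocation posterior end to end. It is a collapsed Gibbs
sampler for a Dirichlet-process mixture of bivariate Gaussians with
conjugate base measure `Σ_g ~ InverseWishart(ν, uνI)`,
`μ_g | Σ_g ~ N(0, Σ_g/a)`: each item in turn is removed from its group and
reassigned to an existing group with probability ∝ (group size) × (the
group's posterior-predictive Student-t density at the item) or to a new
group with probability ∝ α × (the prior predictive). The concentration α and
the hyperparameters are held fixed (defaults `α = 1`, `a = 0.1`, `ν = 4`,
`u = 0.5`) — no hyperpriors — and burn-in/thinning defaults (2000 / 5) are
desk-scale, deliberately far below what a production analysis would use.
The inner loop is numba-compiled; a chain of 2000 + 5×1000 sweeps over
`N = 200` items runs in about a second. Setting `use_likelihood=False`
drops the data term so the chain targets the Chinese-restaurant-process
prior, whose expected number of groups `Σᵢ α/(α+i−1)` provides an exact
calibration check.

## Problem sizes used in the validation battery

Exhaustive-oracle comparisons use 100 random instances with `N ≤ 8`
(`Bell(8) = 4140` candidates) and `T ≤ 50`, greedy with 20 restarts and
`K_up = N`; incremental-update accuracy is checked on 1000 random moves;
recovery uses 100 replicates of the `N = 100`, `T = 500`, `rate = 0.1`
design summarised with `K_up = 8` and 4 restarts; the mixture pipeline uses
10 replicates of the overlapping 4-component preset at `N = 200` with the
sampler defaults above and VI summarisation at `K_up = 20` (the value used
for the heavier runs this design is scaled down from) with 4 restarts.
These sizes complete in a few minutes on one CPU while leaving each check
statistically meaningful.

## Known limitations

* The greedy optimiser guarantees a local optimum only; restarts mitigate
  but do not remove this. Diagnostics (`n_restarts_hit_best`, per-sweep
  traces) expose how reproducible the found optimum was.
* Losses outside the contingency-table family (e.g. generalised Binder with
  asymmetric misclassification costs) are not supported.
* No uncertainty quantification around the point estimate is provided.
* The demo sampler is 2-D only, fixes its hyperparameters, and makes no
  claim of competitive mixing; it is a fixture, not a mixture engine.
* Exhaustive enumeration is intentionally capped at `N = 12`.
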