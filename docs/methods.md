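# Methods

## Model

Each gene is modelled independently.  A latent function `f` over the
sample coordinates (time, pseudotime, or 2-D spatial position) gets a
zero-mean GP prior with one of four kernels:

* rbf: `k(x,x') = sf2 * exp(-||x-x'||^2 / (2 l^2))` — isotropic in any
  input dimension (one shared lengthscale; anisotropy is out of scope);
* linear: `sf2 * <x,x'>`;
* periodic (MacKay): `sf2 * exp(-2 sin^2(pi |x-x'| / p) / l^2)`, 1-D only;
* constant: `sf2` everywhere — the covariance of a random constant level,
  used as the null in every dynamic-vs-constant test.  The rbf kernel
  converges to it as `l -> inf`, which makes those comparisons nested.

Counts enter through a log link, `y_i ~ NB(k_i e^{f(x_i)}, r)` with
`Var[y] = mu + alpha mu^2`, `alpha = 1/r`.  The dispersion is per gene,
shared across samples, and fitted jointly with the kernel
hyper-parameters; it is initialized at 1 and bounded to `[1e-4, 100]`.
The ZINB variant adds dropout mass at zero with Michaelis–Menten
probability `psi(mu) = kappa/(kappa+mu)` (dropout decreases with
expression), `kappa > 0` fitted by ML.  Poisson and Gaussian (on log1p or
Anscombe `2*sqrt(y+3/8)` transformed counts) likelihoods are provided for
comparison.

A fixed empirical offset `f0 = log(mean(y_i/k_i))` is folded into the
effective scale so the zero-mean latent only models relative changes; the
constant-null model receives the same offset, so likelihood ratios are
unaffected by it.

## Inference

* **Gaussian likelihood** — the marginal likelihood
  `N(y | 0, K + s2 I)` is exact; hyper-parameters are optimized by
  L-BFGS with analytic gradients.  Sparse fits use the Titsias collapsed
  bound (dense evaluation; adequate at these N).
* **Count likelihoods, full** — the Gaussian posterior over `f` is
  parameterized as `q = N(m, (K^-1 + W)^-1)` with diagonal `W`
  (Opper–Archambeau), which contains the optimizer of the evidence lower
  bound (ELBO).  The 2N variational parameters are solved by the damped
  fixed-point iteration `W <- -2 dE/dv`, `m <- Sigma (g_mu + W m)`, each
  step accepted only if the ELBO does not decrease, so the recorded ELBO
  trace is monotone.  It typically converges in under 15 iterations and,
  in side-by-side runs, matches or exceeds a long L-BFGS solve of the
  same objective.
* **Count likelihoods, sparse** — a whitened inducing-point posterior
  `q(u) = N(m, S)` at `M` locations (`M = ceil(0.05 N)` by default),
  optimized by L-BFGS with analytic gradients; cost `O(N M^2)` per
  evaluation.  Inducing locations come from a greedy MAP
  M-determinantal-point-process rule — pivoted Cholesky on the kernel
  matrix, ties broken at the lowest index, stopping early if the
  determinant increment falls below 1e-12 — or from k-means centers.
* **Expectations** — `E_q[log p(y|f)]` by Gauss–Hermite quadrature,
  order 20 (order 200 agrees to <1e-6 in tests).
* **Constant-kernel null** — solved with a scalar latent
  (`c ~ N(0, sf2)`, two variational parameters), which is the same model
  family at O(N) cost.
* **Outer loop** — hyper-parameters are optimized in log space by
  Nelder–Mead (bounded, ~60 evaluations) around the inner solver, warm-
  starting the variational parameters between evaluations.  The
  dispersion direction has two basins ("dynamic latent + true alpha" vs
  "constant latent + inflated alpha"), so the search starts once from
  `alpha = 1` and once from `alpha = 0.05` and keeps the better optimum.
  When a dynamic-vs-constant ratio still comes out negative, the dynamic
  fit is restarted from the null's optimum placed at the lengthscale
  boundary; this enforces nestedness up to optimizer noise.
* **Numerics** — covariance factorizations add a relative jitter of 1e-6
  (of the mean diagonal), escalating tenfold to 1e-2 before failing;
  replicated coordinates are kept as separate observations and rely on
  the jitter.  Latent values are clipped at |f| = 45 before
  exponentiation.
* **Safe mode** (off by default, `max_restarts = 5`): a fit is re-started
  from log-uniform random hyper-parameters when the optimizer failed
  numerically or the posterior-predictive median lies on one side of at
  least 90% of the observations; the best objective wins and exhausted
  restarts are flagged `converged = False`, never silently returned.
  One-sided-median detection deliberately does not fire on symmetric
  underfits (a constant median through oscillating data), matching its
  definition.

`BIC = d ln N - 2 L̂` uses the optimized-parameter count `d` and the ELBO
(or exact marginal) `L̂`.

## Tests and FDR

One-sample: `LLR = L̂_dyn - L̂_const`; `p = P(chi2_df >= 2*LLR)` — twice
the log ratio, with `df = 2` by default (the parameter-count difference
is configurable since no canonical value exists for this boundary-nested
comparison).  Two-sample: `LLR = L̂_A + L̂_B - L̂_shared`, `df = 3`.
Storey q-values estimate `pi0` on a lambda grid (0.05–0.95) with a cubic
polynomial smoother evaluated at the largest lambda.  Non-converged genes
are reported with missing statistics and excluded from the FDR
computation, since silently including them biases `pi0`.

The permutation null shuffles the coordinates (one shared permutation per
round across genes) and pools the permuted statistics across genes;
`p = (1 + #{null >= obs}) / (1 + K)` with the add-one estimator.

**Calibration caveat.**  Under a true null the constant model sits on the
boundary of the dynamic family, so `2*LLR` follows a boundary *mixture*
(roughly half point mass at zero), not a chi-squared distribution.  The
chi-squared p-values are therefore conservative — null rejection rates at
p < 0.05 measure 0–2%, and a KS test against uniformity rejects — and the
permutation test inherits the conservatism because most null statistics
tie at zero.  No anti-conservative behaviour was observed in any null
experiment; the practical consequence is reduced power at a given FDR
level, not inflated discoveries.

## Spatial pipeline

Genes with total counts < 3 are dropped, then locations with total
counts < 10, one pass each in that order.  With normalization on, each
gene's counts are regressed on the location totals `T_i` through a
zero-intercept identity-link NB model `y_i ~ NB(beta T_i, r)` (`beta`
log-parameterized, `r` joint ML, Nelder–Mead) and `k_i = beta T_i`
multiplies the GP count mean.  The spatial kernel is an isotropic rbf on
raw coordinate units with the lengthscale initialized at half the median
pairwise distance and then freely optimized (a SpatialDE-style lengthscale
grid was considered and rejected: free optimization performed well on the
synthetic patterns and keeps one code path).

Normalization assumes location totals are dominated by technical size
variation, which holds when thousands of genes contribute.  On a small
synthetic panel the totals carry the expression patterns themselves, so
the detection benchmark runs unnormalized while the dedicated confounding
experiments (smooth spatial size factor multiplied into flat genes)
exercise the normalization.

## Branching

The joint covariance of trunk function `f` and branch function `g`
constrained to cross at `x_b` has within-function blocks `k(x,x')` and the
rank-1 cross block `k(x,x_b) k(x_b,x') / k(x_b,x_b)` (correlation 1 at the
branch point).  Trunk cells always load on `f`; branch-lineage cells load
on `f` before `x_b` and on `g` after.  Lengthscale, amplitude and
likelihood parameters are estimated by two separate per-lineage GP fits,
combined (geometric mean for kernel parameters, arithmetic for likelihood
parameters) and frozen; a per-lineage fit that collapsed onto the
constant solution is dropped when the other is healthy, since it carries
no information about the shared dynamics.  The branch-time posterior is
the normalized likelihood over a uniform grid (default 51 points across
the pooled pseudotime range); for count likelihoods each grid evaluation
re-optimizes only the variational distribution, warm-started from the
previous grid point (verified to match cold starts).

## Synthetic data

*Time courses* follow the benchmark design: 600 genes (scaled down where
noted), 11 equally spaced time points on [0,1], two replicates, half the
genes dynamic.  Dynamic latents are sines `a sin(xb + d) + c` with
`b ~ U[pi/4, 2pi]`, `d ~ U[0, 2pi]`, or natural cubic splines through two
interior control points drawn one per half of the domain (well-separated
knots keep the cubic bounded).  Amplitudes are `a ~ U[0.5, 2.5]` and
baselines `c ~ U[0.5, 2]` (low expression) or `U[3, 6]` (high), all on
the natural-log scale; dispersions `alpha ~ U[0.01, 0.1]` (low) or
`U[1, 3]` (high).  Constant genes sit at the median of a dynamic gene's
latent.  Counts are NB draws from a single seeded generator, bit-for-bit
reproducible.

*Spatial data* places locations on a jittered grid in the unit square;
patterned genes get Gaussian-bump latents with widths `U[0.15, 0.35]` and
the same amplitude range, flat genes a constant, dispersion defaulting to
the low regime (typical of per-spot NB fits); optional confounding
multiplies all means by a smooth spatial size factor.

*Branching data* uses a dynamic trunk sine (amplitude 1.5, frequency 5)
with the branch latent departing linearly after `x_b` — the
model-consistent onset, since the prior standard deviation of `f - g`
grows linearly in `|x - x_b|` — reaching 3 natural-log units at
pseudotime 1, `alpha = 0.2`, pseudotimes `U[0,1]`, half the cells per
lineage.  An earlier quadratic-onset draft hid the branch point from any
estimator (divergence stays within noise until well past `x_b`) and
biased MAP estimates late by ~0.17; the linear onset was fixed before the
benchmark was frozen.

What these simulators do **not** emulate: pseudotime estimation error,
UMI/ambient noise, gene–gene correlation, batch structure, irregular
spatial geometries.  Passing benchmarks therefore demonstrate
correctness of the inference and tests under the assumed observation
models, not robustness to the full messiness of real data.

## Benchmark problem sizes

As run by the test suite and `scripts/acceptance.py` on one CPU:
likelihood oracles on a 30-point random (mu, r, kappa) grid x 40 counts;
Gaussian exactness on 50 datasets of 10–25 points; ROC comparison on 100
genes per dispersion regime (high dispersion at low expression, where
zeros separate count models from the Gaussian; low dispersion at high
expression, where the Poisson's variance restriction binds);
full-vs-sparse concordance on 50 genes at N = 400 cells, M = 20;
branching recovery over 25 replicates of 120 cells; chi-squared
calibration on 200 constant genes and permutation calibration on 50 genes
x 3 rounds (pooled); spatial nulls and detection on 40–60 genes at 100
locations; normalization on 30 confounded flat genes and 50 slope
recoveries at 260 locations.

## Known limitations

* LLRs from variational bounds are conservative: bound slack grows with
  posterior non-Gaussianity, so weak dynamic genes floor at LLR = 0.  In
  the high-dispersion regime (`alpha` up to 3, N = 22) this compresses
  the power advantage of the NB likelihood over the exact-marginal
  Gaussian baseline; an oracle likelihood ratio (true latent and
  dispersion) reaches AUROC ~0.9 where all fitted models reach ~0.7.
* The chi-squared reference for `2*LLR` ignores the boundary mixture (see
  the calibration caveat); p-values are conservative by construction.
* Branching assumes exactly two lineages with known assignments and no
  time warping.
* Per-gene independence throughout; no information sharing across genes
  (e.g. no dispersion moderation).
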