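# Methods

This note records the models implemented in `endoclock`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## The dating model

The posterior sampled by `endoclock.sampler.run_mcmc` is

```
p(t, r, μ, σ² | data) ∝ L(b(t, r)) · p(t) · p(r | t, μ, σ²) · p(μ) p(σ²)
```

over node ages `t` (Ma), rate variables `r`, and clock hyperparameters.

**Age prior `p(t)`.** Calibrated nodes carry soft-bounded uniform
densities; uncalibrated internal nodes are conditionally uniform given the
partial order imposed by the tree (an order-statistics prior). This is a
deliberate simplification of the birth–death node-age kernel used by some
dating software: it is exactly reproducible, has no extra hyperparameters,
and the effective prior it induces can be inspected directly with the
prior-only mode. A birth–death kernel is not provided.

**Soft bounds.** Between the bounds the density is
`h = (1 − p_L − p_U)/(t_max − t_min)`. Below `t_min` the density is the
power form `h (t/t_min)^{θ−1}` with `θ = h·t_min/p_L`; above `t_max` the
exponential form `h·e^{−λ(t−t_max)}` with `λ = h/p_U`. Both tail parameters
are fixed by continuity at the bound, and the three pieces integrate to
`p_L`, `1 − p_L − p_U`, `p_U`. Setting a tail probability to zero gives a
hard bound. Minimum-only calibrations (fossils give a floor but no
ceiling) are the flat density above `t_min` with the same power tail below
(`θ = (1 − p)/p`, i.e. tail mass `p/(1−p)` relative to a unit-height
interior of length `t_min`); they are improper in isolation and therefore
only admitted together with a root calibration carrying a finite maximum.

**Clocks.** Under the autocorrelated (AR) model every node has a log-rate;
a child's log-rate is `N(log r_parent − σ²Δt/2, σ²Δt)`, making the child's
rate a martingale given the parent's. The branch rate is the arithmetic
mean of the endpoint node rates (a geometric-mean variant is switchable via
`ClockConfig.branch_rate`; it changes the likelihood only mildly and is off
by default). The root node's log-rate needs its own prior, which the
theory does not fix: `N(log μ − σ²τ₀/2, σ²τ₀)` with `τ₀ = 500` Ma
(`root_var_time`), i.e. the dispersion the Brownian process would
accumulate over half a typical root age. Under the independent-rates (IR)
model each branch's log-rate is iid `N(log μ − σ²/2, σ²)` with σ²
dimensionless.

**Hyperpriors.** `μ ~ Gamma(shape 2, mean 2e−4 /site/Ma)` and AR
`σ² ~ Gamma(2, 5e−4 /Ma)` (IR: mean 0.3). These are visible, overridable
defaults (`ClockConfig`) sized to trees a few thousand Ma deep with branch
lengths of order 0.1 substitutions/site; the `Sigma` sensitivity preset
multiplies the σ² prior mean by 5. `FixedPrior` pins a hyperparameter.

**Likelihood.** The quadratic expansion of the sequence log-likelihood
around per-partition branch-length estimates, on the plain branch-length
scale, summed over partitions; branch lengths come from `b = r × Δt`. The
package does not implement substitution-model likelihoods at all — that is
its major scope decision. Synthetic partitions are generated as
`b̂ ~ N(b_true, Σ)` with `H = −Σ⁻¹`, `g = 0`, which makes the approximation
*exact* and lets the tests isolate sampler correctness. An exact
per-branch Poisson-count likelihood is included purely as a small-scale
oracle. All units are Ma and substitutions/site end to end; no internal
rescaling is performed (double precision is ample at these magnitudes).

## The sampler

Metropolis-within-Gibbs, one iteration = one sweep:

1. each internal non-root age by a reflected-normal slide inside
   `(max child age, parent age)` — the window edges do not move during the
   update, so the proposal is symmetric;
2. the root age by a reflected-normal step above its oldest child;
3. every rate variable by a normal step in log-rate space;
4. `μ` and `σ²` by log-scale random walks (with the log-normal Jacobian);
5. a subtree scaling move per internal non-root node: all ages inside the
   subtree ×`c`, all its log-rates −`log c`, with `c = e^u`,
   `u ~ U(−λ_i, λ_i)`. Branch lengths inside the subtree are invariant, so
   only the stem branch touches the likelihood; the Jacobian is
   `c^{#internal nodes scaled}`;
6. a whole-tree scaling move (the same construction applied at the root,
   where it is the classic "mixing" move: likelihood exactly invariant).

The subtree moves matter: ages and rates are nearly perfectly
anti-correlated locally (only their product is data-constrained), and with
elementwise moves alone the worst-parameter ESS stalled near 10 per 3×10⁵
sweeps and credible intervals undercovered. With them, the study-scale
preset reaches ESS > 15,000 for every parameter on the 20-leaf benchmark.

Proposal scales adapt every 200 sweeps during burn-in only, targeting
~30% acceptance (within the standard 20–40% band); after burn-in the
kernel is fixed, preserving the stationary distribution. Scale moves can
be disabled (`disable_scaling_moves`) to verify by comparison that they
leave the stationary distribution unchanged. The starting state midpoints
each calibration and propagates the age ordering; rates start at the prior
mean. Sampling is fully deterministic given `MCMCSettings.seed`.

Chain presets: `MCMCSettings.paper()` = burn-in 200,000, sample every 100,
20,000 samples; `MCMCSettings.desk()` = 20,000 / 10 / 2,000 for tests and
experiments. The stored log-posterior is recomputed from scratch at every
saved sample, which also resets the incremental likelihood caches.

## Diagnostics

* **Infinite-sites regression**: OLS of 95% HPD width on posterior mean
  age. With unlimited data the points fall on a line whose slope is the
  calibration-induced uncertainty per Ma; a lower slope = more precise
  dating.
* **Prior/posterior comparison**: per-node two-sample KS statistic and mean
  shift between a prior-only chain and the posterior; nodes with KS below
  0.1 are flagged as uninformative (dates driven by calibrations alone).
* **Composite posteriors**: equal-weight pooling (resampling each analysis
  to a common size) across the scheme registry — best-practiced plus
  `Phan` (Phanerozoic minima only, cutoff 541 Ma), `Max-1`/`Max-2`
  (tagged maxima dropped to minimum-only), `SinglePartition`
  (precision-weighted partition merge), `IR`, and `Sigma`. Which six
  analyses make a published composite is an inference from figure labels,
  not something the package can know; the registry makes the choice
  explicit and auditable.
* **Root sweep**: one dating run per root-maximum grid value (shared seed
  policy, internal calibrations fixed), with per-clade OLS slopes of
  posterior mean age against the root maximum. An optional two-chain check
  per grid point raises on non-convergence.

## Host-lifestyle ASR

Two-state CTMC with rates per unit branch length on the input tree's own
branch lengths (no clock assumption). The root state distribution defaults
to the stationary distribution `π = (q_PA, q_AP)/(q_AP + q_PA)`; uniform is
available. `?` tips contribute flat partials. Rate priors are independent
exponentials with default mean `2 / tree length` (about two expected
transitions a priori — weakly informative for characters that change
rarely); experiments with a known simulation scale should pass a prior
matched to that scale. Stepping-stone sampling uses a K=32 rung ladder with
`Beta(0.3, 1)` quantile spacing (dense near the prior), per-rung
warm-started Metropolis chains, and exact iid prior draws at β=0. The
reported Bayes factor is `2 × (logML_free − logML_equal)`; conventions
differ between packages, so the factor of two is deliberate and documented.

A note on attainable evidence: with ~20 realized transitions on a 100-tip
tree, the maximum-likelihood contrast between free and equal rates is
median ≈ 5–8 (2ΔlogL units) even when the true rates differ ten-fold; the
marginal-likelihood Bayes factor is necessarily smaller. Crossing the
"very strong" threshold of 10 in simulation requires roughly 40–60
transitions. Published analyses reporting much larger values reflect data
with more transitions, not a different estimator.

## Synthetic data

`ScenarioSpec` describes a stated world: a symbiont clade (default 12
tips) and a fossil-rich host-analog clade (8 tips) joined at the root
(default 1800 Ma, between the 3000–1000 Ma root brackets typical of this
problem); reconstructed-birth-death subtree shapes (node ages drawn from
the conditioned density, pure-birth rate 2e−3/Ma by default); AR clock
rates from the model's own prior; and branch-length estimates with 10%
relative Gaussian noise in two partitions. Calibration brackets are drawn
around the true ages (`min = truth × U(0.6, 0.9)`,
`max = truth × U(1.1, 1.6)`), so every interval contains its truth;
`mito_like` placement keeps both bounds on 3–5 host-clade nodes, while
`cyano_like` strips the internal maxima and leaves the root maximum as the
only ceiling. Matched pairs share tree, rates and noise exactly and differ
only in placement, so the root-sweep contrast is attributable to
calibration design alone.

For coverage experiments, `draw_prior_predictive` replaces the birth-death
truth with a draw from the sampler's *own* joint prior (ages via a short
prior-only chain, hyperparameters from their gammas, rates from the clock
cascade) and uses a noise SD that is constant across replicates — if the
noise scaled with the drawn truth, the likelihood's covariance would leak
information the model ignores and nominal coverage would not be implied.

What a green test establishes: the sampler targets exactly the model it
claims, on data where the quadratic likelihood is exact. What it does not:
robustness to substitution-model misspecification, alignment error,
saturation, or topology error — real-sequence effects that are outside
this package's scope (tree inference, alignment and sequence simulation
are deliberately not implemented).

## Numerical details

* Age ordering is strict with ε = 1e−9 Ma; zero-duration branches are
  rejected everywhere.
* HPD: shortest contiguous window containing ⌈0.95 N⌉ sorted samples.
* ESS: `N / (1 + 2Σρ_k)` with autocorrelations summed to the first
  non-positive term; constant chains report 0 with a warning.
* Two-chain check: relative difference of posterior means against the pair
  mean magnitude, default tolerance 2%.
* Pruning likelihoods scale partials by their maximum per node and
  accumulate logs, so 100+ tip trees do not underflow.
* The MCMC kernel is numba-compiled (`cache=True`); the first call in a
  fresh environment costs ~15 s of compilation.
* Node identity everywhere is the post-order integer id assigned at parse
  time (children before parents, root last, branch = child node id).
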