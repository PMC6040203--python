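# Methods

This note records the model implemented by `dsbayes`, the numerical
choices behind it, and the limits of what the test suite demonstrates.

## Model

For `k` parallel studies, observations `y_i | θ_i ~ f(y | θ_i)` are
drawn from one of four likelihoods with its conjugate anchor prior
`g(θ; α, β)`:

| likelihood | anchor g | marginal f_G | posterior π_G |
|---|---|---|---|
| Bin(n_i, θ) | Beta(α, β) | beta-binomial | Beta(α+y, β−y+n) |
| Poi(θ) | Gamma(α, scale β) | NB, p = 1/(1+β) | Gamma(α+y, β/(1+β)) |
| N(θ, s_i²) | N(μ, τ²) | N(μ, s_i²+τ²) | N(λμ+(1−λ)y, (1−λ)s_i²), λ = s²/(s²+τ²) |
| Exp(θ) | Gamma(α, scale β) | Lomax αβ/(1+βy)^{α+1} | Gamma(α+1, β/(1+βy)) |

The gamma hyperparameter β is a *scale* throughout (prior mean αβ).
The latent effects follow a corrected prior

    π(θ) = g(θ; α, β) [1 + Σ_{j=1}^m c_j T_j(θ; G)],

with `T_j = Leg_j ∘ G` the orthonormal shifted Legendre polynomials of
the prior rank transform.  Because each `T_j` (j ≥ 1) integrates to zero
under G, π integrates to 1 for *any* coefficient vector; the bracket on
the rank scale is the U-function `d(u)`, the prior density ratio.  The
series is deliberately truncated low (`m_max = 8` by default): the model
class is a *neighbourhood* of the elicited anchor, not a free-form
density estimator.

The bracket is not constrained to be nonnegative.  Density evaluation
returns the signed value (with a warning) so the diagnostic shape
survives; sampling and the KL diagnostic truncate negative regions at 0
and renormalise.  This keeps the estimating equations linear in the
coefficients while keeping every sampled object a proper distribution.

## Hyperparameters

`fit_mle` maximises the exact marginal likelihood `Π_i f_G(y_i)`
(type-II maximum likelihood) by Nelder–Mead on `(log α, log β)`.  The
normal family is profiled instead: for fixed τ² the optimal μ is the
precision-weighted mean with weights `1/(s_i² + τ²)`, leaving a bounded
1-D search over τ² in `[0, 10·var(y)]`; the τ² = 0 boundary is
admissible and checked explicitly.  For very small k a fixed start such
as the Jeffreys Beta(1/2, 1/2) is preferable to an MLE; `jeffreys()`
provides it and the CLI accepts any user-supplied pair.  Tied
observations are grouped before evaluation, so frequency-table data
(thousands of identical counts) costs one likelihood term per distinct
value.

## Coefficient estimation

If the θ_i were observed, `c_j` would be the sample mean of
`T_j(θ_i; G)`.  They are not, so each term is replaced by its posterior
mean and the resulting map is iterated to self-consistency:

    c_j ← k⁻¹ Σ_i E_LP[T_j(Θ_i; G) | y_i],

where `E_LP` is the posterior expectation under the *current* corrected
prior (evaluated in closed ratio form from the conjugate moments
`E_G[T_j | y_i]` and `E_G[T_j T_l | y_i]`, which are precomputed once
per distinct observation).  Starting from `c = 0`, the first sweep is
the plain conjugate-posterior average; subsequent sweeps undo the
attenuation that posterior averaging applies to the latent
coefficients.  All orders update simultaneously; iteration stops when
the largest coefficient change falls below `tol = 1e-3` or after
`max_iter = 100` sweeps.  Hyperparameters stay fixed throughout: the
anchor is the object being corrected, not re-fit.

After the iteration the vector is sparsified once by BIC: order the
coefficients by decreasing magnitude and keep the prefix maximising
`Σ_{j≤m} c_(j)² − m log(k)/k`, with the empty set always admissible.

**Identifiability and stopping.**  The update is a nonlinear
deconvolution, and the information the marginal carries about order j
decays quickly with j (it is governed by the variance of
`E_G[T_j | Y]`, which shrinks as the likelihood gets less informative).
Consequently high-order coordinates converge slowly, amplify sampling
noise, and for small k can leave the Fourier ball
`|c_j| ≤ sqrt(2j+1)` entirely.  When an update leaves the ball (or
drives a marginal correction factor non-positive) the fit rolls back to
the last in-bound iterate, flags `diverged`, and smooths that iterate.
The finite iteration cap is therefore also a regulariser: the reported
coefficients depend (mildly for the low, well-identified orders;
strongly for the high ones) on the stopping point.  The BIC step prunes
most of the amplified-noise orders, but with few studies the retained
set can still be larger than a human analyst would keep; the
`raw_coef`, `bic_table` and `trajectory` fields of `FitResult` expose
everything needed to inspect a fit.

## Quadrature

All conjugate posterior moments of basis functions are computed by
substituting θ = Q_post(v), v ∈ (0, 1), so the integrand becomes the
bounded smooth function `Leg_j(G(Q_post(v)))` against the uniform
measure — exactly normalised for every observation, including posteriors
concentrated deep in the anchor's tail where quadrature on the
`u = G(θ)` scale itself would miss the mass.  Because `G ∘ Q_post`
typically has power-law behaviour at the endpoints, the nodes are
Gauss–Legendre points pushed through the cosine map
`v = (1 − cos πt)/2`, which clusters them quadratically at 0 and 1; 128
nodes (the default) give ~1e−9 accuracy on these integrals, and the
test suite checks stability under node doubling.

## Downstream inference

* **Stein / parametric EB**: the conjugate posterior mean, a weighted
  average of the study MLE and the anchor prior mean.
* **Elastic-Bayes**: the corrected posterior mean in ratio form; equal
  to the Stein estimate when no coefficient survives smoothing.
  Posterior medians come from grid inversion of the corrected posterior
  CDF (2001 points), modes from the grid argmax refined by bounded
  scalar maximisation.
* **Robbins**: `(y+1) N_{y+1}/N_y` from the empirical claim-frequency
  table; undefined (None) at empty cells and the table edge.
* **Prior modes**: grid scan (2001 points over the support, or the
  central 99.9% of G for unbounded supports) followed by local bounded
  refinement; boundary-only maxima are flagged rather than reported.
* **Mode standard errors**: smooth parametric bootstrap.  Each replicate
  draws k effects from the fitted prior via the rank-scale inverse-CDF
  sampler (10,000-point grid), regenerates observations with the
  original exposures, re-runs the full coefficient fit, and matches
  replicate modes to the original ones by nearest location within half
  the original inter-mode gap; the SE is the standard deviation of
  matched locations (default B = 200).  Since every replicate re-fits
  the whole pipeline, these SEs include estimation noise in the
  correction itself, and with few modes-per-replicate matched counts are
  reported alongside.
* **Study grouping**: K-means (scipy, 10 seeded restarts, best
  within-cluster SS) on the per-study posterior modes, labels ordered by
  centroid.

## Synthetic data

`simulate_ds` draws study effects from any corrected prior by inverse
CDF on the rank scale and pushes them through the likelihood — the
generator used for recovery tests (a third-order correction of −0.5 on
a Beta(2.3, 14.1) anchor is recovered within ±0.1 from k = 2000
binomial studies of 20 trials).

`simulate_pharma` emulates a historical-control scenario with tunable
prior–data conflict: effects from the two-component mixture
`η·Beta(5, 45) + (1−η)·Beta(30, 70)`, k = 100 studies of 60 trials
each, and a new study `y_new ~ Bin(50, 0.3)` whose generative rate 0.3
is the estimand.  Per replicate (250 by default; 50 in the test suite)
the MLE, parametric-EB and Elastic-Bayes estimates of the new rate are
scored against 0.3.  Replicates whose coefficient iteration diverges
are scored with the rolled-back smoothed fit, so every replicate
contributes.  As η grows the anchor misfits more and the Elastic-Bayes
estimate's MSE advantage over parametric shrinkage widens — the
qualitative signature the tests assert at η = 0.4.

What the generators do *not* emulate: overdispersion beyond the mixture
structure, covariate-driven heterogeneity, dependence between studies,
exposure-informative selection, or reporting bias.  Tests passing on
this synthetic world show the estimating machinery is correct under the
stated model, not that the model fits any particular real dataset.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `m_max` | 8 | highest basis order fitted |
| `tol` | 1e-3 | max absolute coefficient change to declare convergence |
| `max_iter` | 100 | iteration cap (also acts as regularisation) |
| `nodes` | 128 | quadrature nodes per posterior |
| `B` | 200 | bootstrap replicates for mode SEs |
| sampler grid | 10,000 | inverse-CDF resolution on the rank scale |
| mode grid | 2001 | density scan resolution |

## Known limitations

* High-order coefficients are weakly identified; their fitted values are
  stopping-point dependent and should be read together with
  `converged` / `diverged` and the BIC table.  Published analyses of the
  bundled datasets report sparser corrections than this implementation's
  defaults produce on two of them; the low-order, well-identified
  structure (which basis orders carry the correction, and the resulting
  prior shape near its modes) is the robust part of the output.
* A heavily negative bracket means the truncated series is a poor
  density in that region; diagnostics remain meaningful, but sampled
  quantities implicitly use the truncated-renormalised prior.
* The Poisson-gamma anchor cannot express heavy tails beyond the gamma's
  by a bounded multiplicative correction: posterior means under any
  corrected prior stay within the hull of the conjugate posterior's
  support, so extreme-tail estimates move little even when the correction
  is large.
* The exponential–gamma family is provided for completeness and is
  exercised only by the invariant tests; it has no bundled worked
  example.
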