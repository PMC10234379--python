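# Methods

## The Kimura distribution and its numerical evaluation

The distribution of heteroplasmy *h* after pure neutral drift from an
initial fraction *p* is mixed: probabilities of loss (*h* = 0) and
fixation (*h* = 1) plus a continuous density on (0, 1). With drift
parameter *b* (the retention factor; *b* = e^(−t/2N) in the underlying
Wright–Fisher diffusion), the density is the eigenfunction expansion

    φ(h) = Σ_{i≥1} i(i+1)(2i+1) p q F_i(p) F_i(h) b^{i(i+1)/2},
    F_i(x) = ₂F₁(1−i, i+2; 2; x),   q = 1 − p,

and the loss/fixation masses are

    P(0) = q + Σ (2i+1) p q (−1)^i F_i(q) b^{i(i+1)/2},
    P(1) = p + Σ (2i+1) p q (−1)^i F_i(p) b^{i(i+1)/2}.

Numerical choices:

* **Polynomial evaluation.** F_i is a degree-(i−1) polynomial; it is
  evaluated through the Gegenbauer identity
  F_i(x) = 2/(i(i+1)) · C_{i−1}^{3/2}(1−2x), which scipy evaluates
  stably at high degree (the C values are O(i²)-bounded on [−1, 1],
  avoiding the blow-up of naive hypergeometric recursion).
* **CDF.** Term-wise closed-form integration via
  C_n^{3/2}(z) = P'_{n+1}(z) (Legendre), giving
  ∫₀ʰ F_i = (1/(i(i+1)))(1 − P_i(1−2h)). A quadrature route exists in
  the tests as an independent cross-check.
* **Truncation.** The series is cut when the term bound
  (2i+1)·(i(i+1)/2)·b^{i(i+1)/2} falls below 1e−12, with a hard cap of
  1000 terms; parameter searches are bounded at b ≤ 1 − 1e−4
  (n_b ≤ 10⁴), which keeps the required term count under the cap.
  When 1 − b < 1e−6 the distribution is treated as the degenerate
  point mass at p.
* **Cancellation floor.** Deep in the tails the alternating series
  cancels below machine precision; since the true density is strictly
  positive on (0, 1) for interior p, computed densities are floored at
  1e−16 times the sum of absolute term magnitudes rather than being
  allowed to round to ≤ 0. Observations whose probability is genuinely
  zero (e.g. interior observations under p = 0) contribute a −1e10
  sentinel to the log-likelihood instead of −∞, keeping optimizers
  finite.
* **Validation.** Normalization (masses + ∫φ = 1), the moment
  identities μ = p and σ² = p(1−p)(1−b), CDF monotonicity, and the
  allele-relabeling symmetry are asserted to 1e−6 across a parameter
  grid; the masses and CDF were additionally checked against a direct
  Wright–Fisher binomial simulation during development.

**Moments.** The raw moments under pure drift follow the Wright–Fisher
moment recursion dE[xⁿ]/ds = n(n−1)(E[xⁿ⁻¹] − E[xⁿ]) (s = t/4N), whose
eigenvalues give powers b, b³, b⁶ for orders 2–4:

    E[x²] = p − pq·b
    E[x³] = p − (3/2)pq·b + pq(1/2 − p)·b³
    E[x⁴] = p − (9/5)pq·b + pq(1 − 2p)·b³ + pq(pq − 1/5)·b⁶

μ₄ follows by expansion; the tests verify it against quadrature over
the full mixed distribution.

**Sampling** is exact inverse-CDF: a uniform draw is mapped to 0 or 1
inside the point masses, otherwise inverted through a 4097-point
monotone table of the continuous CDF (piecewise-linear inversion; the
induced CDF error is far below sampling noise at every sample size used
here).

## Fitting

Three estimators, one deterministic optimizer: a coarse grid (step
0.01 on [0.001, 0.999] for each free parameter) seeds three rounds of
21-point local grid refinement (final resolution ~1e−5). Ties break to
the lowest-index grid point, so fits are bit-identical across runs.
The method-of-moments parameterization (and, for min-KS, the ML fit) is
always included as an extra refinement seed, which guarantees the
dominance invariants loglik(ML) ≥ loglik(MoM) and KS(min-KS) ≤
KS(MoM/ML) by construction. Likelihood and KS objectives over parameter
grids share their Gegenbauer/Legendre factors across the whole grid,
which is what makes grid search practical.

MoM estimates of b outside [0, 1] are clamped and flagged rather than
raised, so batch runs survive pathological sets. All-identical samples
short-circuit to the degenerate fit (b = 1) with a degeneracy flag.

**Which fit for the plant example.** For the 24-offspring dataset the
package's headline fit is the free-(p, b) maximum likelihood fit. With
p pinned to the mother's measured 0.81 the profile maximum sits at
b ≈ 0.13 — the mother's single measurement is itself a sample, and
pinning p to it visibly degrades the fit of an offspring distribution
whose own evidence favours a smaller p. The free fit (p̂ ≈ 0.26,
b̂ ≈ 0.19, n̂_b ≈ 1.24) is both the better-supported model and the one
whose likelihood-based 95% interval (0.09–0.33 on b) matches the
published analysis of this dataset. The fixed-p option remains
available (`fit_ml(sample, fixed_p=...)`) for settings where the
reference really is reliable.

**Confidence intervals for b** (`confint_b`): the default inverts the
likelihood-ratio statistic on the profile log-likelihood
({b : ℓ(b) ≥ ℓ(b̂) − χ²₁(0.95)/2}), which is asymmetric and respects
the [0, 1] boundary; alternatives are a Wald interval from the
numerical curvature of the profile log-likelihood ("fisher", falling
back to bootstrap at boundary fits) and a seeded percentile bootstrap
(1000 refits by default). Bottleneck intervals are the monotone
transform n_b = 1/(1−b) of the b endpoints.

## KS testing

The KS distance is the sup-norm between the sample ECDF and the mixed
theoretical CDF; candidates are every data value plus the atoms at 0
and 1, each compared before and after its jump (both functions are
right-continuous step/smooth, so the sup is attained there). Because
parameters are mixed-type and typically data-fitted, no analytic null
applies; the p-value is Monte Carlo: simulate B datasets (default
5000) under the tested parameterization, report
(#{D_sim ≥ D_obs} + 1)/(B + 1) — ties count toward rejection, and the
+1/+1 convention avoids p = 0 — together with the exact binomial 95%
interval on the tail fraction. A two-sample mode (data ECDF vs the
ECDF of one large reference sample) replicates the historical
ensemble-based formulation behind a flag; the one-sample mode is the
default because it is exactly defined.

Testing a distribution fitted on the same data is statistically
generous: a small p-value is informative, a large one is not a clean
acceptance. The min-KS fit gives the most charitable assessment of
whether *any* Kimura distribution is compatible with the data. For the
structurally un-fittable 50×0 + 50×0.9 dataset, the minimum achievable
KS distance is exactly 1/4 (the ECDF jump from 0.5 to 1 at 0.9 cannot
be split better than F(0.9) = 3/4), and the Monte Carlo test rejects at
its floor: p = (0+1)/(B+1), i.e. ≈ 0.01 at B = 100 and ≈ 2e−4 at
B = 5000.

## Nonparametric variance uncertainty

h₄ is the unique unbiased symmetric estimator of μ₄ from sample
moments; V̂(s²) = (h₄ − (n−3)/(n−1)·s⁴)/n plugs it into the population
identity for the variance of the sample variance. Two caveats are
deliberate properties, not bugs: V̂ can be negative in small samples
(it is returned raw with a flag so simulation averages stay unbiased;
the CLI also displays the floored value), and it is not exactly
unbiased — E[s⁴] = σ⁴ + V(s²) implies E[V̂] = V(s²)(1 − (n−3)/((n−1)n)),
about 4.5% low at n = 20 — which the calibration tests assert exactly.
The historical D₄ expression is not implemented: it is the expectation
of the sample moment m₄ (its right-hand side contains μ₄ itself), not
an estimator; `moments.d4` raises with a pointer to h₄.

Bootstrap: B resamples with replacement; resampling biases dispersion
low by (n−1)/n, so the point estimate multiplies the mean resample
variance by n/(n−1); the spread of the corrected resample variances is
the uncertainty. Jackknife: closed-form leave-one-out variances and the
standard (n−1)/n · Σ(θᵢ − θ̄)² error. Spreads are standard-error-like;
turning them into confidence intervals requires a parametric choice
(±1.96·s.e. assumes normality), which the API leaves to the caller.

## Group comparison

Bottleneck sizes cannot be compared by t-test (a sample variance is not
normal; its reciprocal less so). Instead two nested models are fitted:
per-set p with per-group b (full) versus per-set p with one shared b
(null). The p's separate conditionally on b, so maximization is nested
one-dimensional profiling — each set's p profiled on the same
deterministic grid-plus-refinement, an outer search over b — and
Λ = −2(ℓ₂ − ℓ₁) is referred to χ² with (groups − 1) degrees of
freedom. Group bottleneck intervals invert the χ²₁ cutoff on the
group's b-profile.

Calibration: with per-set n = 20 the type-I rate sits at the nominal
5% (measured 4% over 150 null replicates); with very small sets the
χ² approximation inflates it (≈13% at n = 2×2 pairs of 5 — measured
during development), so small-sample p-values near the threshold
deserve caution. Power is nonetheless high for genuinely different
drift regimes: tight pairs (b = 0.97) versus wide pairs (b = 0.5) are
separated in the majority of replicates even with two observations per
set.

## Synthetic data

All calibration and power studies draw from the package's own exact
Kimura sampler (`simulate_grouped`), seeded and reproducible. The
generator emulates ideal neutral-drift sampling: independent draws,
exact values in [0, 1], no measurement error, rounding, or selection.
Real heteroplasmy data add measurement noise and value rounding — the
`perturb` utility exists to probe exactly that sensitivity — so passing
calibration here certifies the statistics under the model, not
robustness to assay artefacts. Study sizes used by the test suite:
type-I calibration of the KS test at n = 50, B = 400 over 200
replicates; CI coverage at n = 50 over 500 replicates (p fixed at
truth, so coverage isolates the b-interval); h₄ unbiasedness at
n = 10 over 10⁵ replicates; LRT calibration at n = 20 per set over 150
replicates. These sizes give Monte Carlo standard errors comfortably
inside the asserted bands while keeping the suite quick on one CPU.

## Known limitations

* Kimura's selection, fluctuating-selection and truncated variants are
  out of scope; only the neutral-drift distribution is implemented.
* The KS p-value after a same-data fit is a diagnostic, not an exact
  test; no correction for parameter estimation is attempted.
* Percent auto-detection divides a whole column by 100 when any value
  exceeds 1; columns genuinely mixing scales cannot be disentangled.
* b is capped at 1 − 1e−4 in searches (bottlenecks above 10⁴ units are
  reported as degenerate fits).
* Reference heteroplasmy measurements are treated as plug-in constants
  when requested, though they are themselves samples.
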