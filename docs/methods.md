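# Methods

## Model and scope

The setting is a test of a simple null hypothesis H₀: μ = μ₀ for the mean
of an (at least approximately) normally distributed test statistic, the
situation behind most z-, t- (large sample) and χ²-based procedures in the
medical literature. The package computes *lower bounds* on the Bayes
factor BF = f(data | H₀)/f(data | H₁), minimized over a family of prior
densities for μ under H₁, and propagates them through Bayes' theorem

    posterior odds of H0 = prior odds of H0 × BF.

Because the minimized BF is a lower bound, the derived posterior
probability of H₀ is a lower bound too, the solved-for prior is the
*maximum* prior compatible with a posterior target, and the solved-for
P value is the *maximum* P value. Exact Bayes factors for a specific
prior are out of scope except in the power analysis (below), where the
prior is fully specified.

## The calibrations and their conventions

* **ELS** (point mass at the MLE): BF = exp(−z²/2). The minimizing prior
  sits on one side of the null, so the z entering the bound is the
  *one-tailed* normal quantile of the P value: z = Φ⁻¹(1 − p). This
  convention, rather than the two-tailed quantile, reproduces the
  reference values reported in the literature for this calibration
  (20.5 / 6.3 / 0.8% at q = ½).
* **Berger–Sellke symmetric** (scenario 1): the least favorable symmetric
  prior is a two-point mass at ±μ, giving
  BF = φ(z) / max_{μ≥0} ½[φ(z−μ) + φ(z+μ)] with the *two-tailed* z.
  Berger and Sellke define this scenario by its prior family rather than
  a display formula, so the bound is implemented as the
  least-favorable-prior maximization itself and validated against the
  literature reference values and a brute-force grid oracle.
* **Berger–Sellke unimodal symmetric** (scenario 2): the least favorable
  member is uniform on [−K, K]:
  BF = φ(z) / max_{K>0} [Φ(K−z) − Φ(−K−z)]/(2K). Same validation route.
* **Berger–Sellke normal** (scenario 3): BF = √e · z · exp(−z²/2) for
  z ≥ 1. Below z = 1 the unconstrained minimizing prior variance would be
  non-positive, so the bound is 1; the cap is continuous because
  √e · exp(−½) = 1.
* **SBB**: treats the P value itself as the statistic; over decreasing
  beta densities of p under H₁ the bound is BF = −e·p·ln p for p < 1/e
  and 1 above. It is the package default (and the nomogram's default
  middle-axis scale) because it is not tied to a specific test statistic.
* **χ²**: BF = (x/ν)^(ν/2) · exp(−(x−ν)/2) for x ≥ ν, else 1. The
  closed form is reconstructed from three identities it must satisfy —
  equality with the normal-prior bound at ν = 1 (x = z²), with SBB at
  ν = 2 (x = −2 ln p), and convergence to ELS as ν → ∞ — and those
  identities are enforced as tests. Evaluation is done in log space so
  very large ν stays stable. The ELS limit is O(ν^−½): at ν = 10⁴ the gap
  is ~1×10⁻⁴ at p = 0.001 but ~2×10⁻³ at p = 0.05, so the "within 10⁻³"
  check is asserted for p ≤ 0.01 alongside an explicit convergence-rate
  check.

One-tailed P values above 0.5 have a negative quantile and are rejected
by the scale conversion; in the ELS dispatch such values map to z = 0,
i.e. no evidence.

## Numerical choices

* The two optimization-based bounds use bounded scalar maximization
  (`scipy.optimize.minimize_scalar`, bracket [10⁻⁸, max(20, 4z)],
  xatol 10⁻¹⁰). The objectives are unimodal over the bracket; the
  boundary candidate μ, K → 0 (marginal density φ(z)) is always compared
  so the bound caps at exactly 1 for weak evidence. Tests cross-check
  against a dense grid search (step 10⁻⁴ over [0, 20]) to 10⁻⁶ relative.
* The inverse map BF → P value uses the lower Lambert-W branch for SBB
  (exact), and Brent root finding on the (monotone) z- or χ²-statistic
  scale otherwise, with tolerances tight enough that forward/backward
  round trips hold to 10⁻⁹ on the Bayes factor and ~10⁻⁷ relative on p.
* Probabilities are proportions in (0, 1) internally; priors of exactly
  0 or 1 are rejected (their odds are undefined and no Bayes factor moves
  a dogmatic prior). Percent display rounds half-away-from-zero, one
  decimal by default, so comparisons against published percentages are
  well defined.

## The nomogram

Three parallel vertical axes at abscissas 0, ½, 1 carry the ordinates

    y_left(q)  = −logit(q),   y_mid(p) = ½·ln BF_min(p),   y_right(π) = logit(π).

A straight edge is exact, not approximate: the chord from (0, −logit q)
to (1, logit π) has midpoint ordinate [logit π − logit q]/2, which equals
y_mid(p) precisely when logit π = logit q + ln BF — Bayes' theorem on the
log-odds scale. The ½ factor is what places the evidence axis midway, so
no projective fitting is needed.

The middle axis covers only p < 1/e (above it the SBB bound is 1 and
there is nothing to move); its ordinates are all ≤ 0, encoding that the
chart only ever moves the posterior *below* the prior — P values measure
evidence against, never for, the null — which is also why the left and
right probability scales are deliberately different. The prior axis
increases downward (the Fagan-chart convention). Default ticks
(probability axes 0.001–0.999, P axis 10⁻⁶–0.3) and the ±7 logit clip are
package choices. SVG is the
canonical output — written directly, with no timestamps or generated ids,
so a fixed geometry and line list renders byte-identically — and PNG is
rasterized from the same geometry via matplotlib.

## Posterior probability versus power

Under a fully specified normal prior for the effect, centered at the null
with standard deviation τ in units of the minimum clinically important
difference (MCID), the exact Bayes factor at an observed two-tailed z is

    BF(z, g) = √(1+g) · exp(−(z²/2)·g/(1+g)),   g = (τλ)²,

where λ = z₁₋α/₂ + z_power is the MCID in standard-error units implied by
a design with two-sided level α and the given power (the standard
sample-size identity; the two-sided rejection probability is approximated
by its near tail, standard for moderate effects). That link between power
and the prior spread on the z scale is forced by the design parameters
(α = 5%, τ in MCID units) and validated by the identity that minimizing
BF(z, g) over g recovers the normal-prior bound at g = z² − 1 (z ≥ 1) —
the curve of posterior against power therefore touches the bound at one
interior power and rises on both sides (a U-shape). For powers in the
ordinary 40–95% range the actual posterior stays within a small factor of
the bound; the ratio < 1.5 check in the tests is this package's
operationalization of "close", since the qualitative claim carries no
printed number. The default power grid is 0.01–0.99 in steps of 0.005,
restricted to powers feasible at the scenario's α (λ > 0); explicitly
supplied grids are taken literally and infeasible entries raise.

The closed-form BF is cross-checked in tests against 1-D numerical
integration of the normal marginal density (agreement to 10⁻⁸).

## Known limitations and documented discrepancies

* For the "maximum P value" usage mode (prior 50% → posterior 0.3%), the
  exact SBB solve gives p ≈ 1.23×10⁻⁴ (0.0123%). A value of 0.014%
  (1.4×10⁻⁴) has circulated for this example from reading the chart by
  eye; it is not consistent with the exact arithmetic, and this package
  reports the exact solve.
* The bounds assume the normal (or χ²) sampling model behind the test
  statistic; small-sample t statistics, composite nulls, and
  multiple-testing adjustments are out of scope.
* Minimum bounds are *optimistic for the alternative* by construction:
  the actual posterior probability of H₀ under any honest prior is at
  least the reported minimum, a point the power analysis quantifies.
* The CLI is deterministic end to end; there is no randomness anywhere in
  the computations.
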