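# Methods

## Model

A quantitative trait is decomposed additively, Z = Y + ξ: Y is the breeding
value with population law p₀(y) (variance σ²_A when finite), ξ an
independent environmental deviation with kernel f, required to be symmetric
with zero mean so that E(Z) = E(Y) and, for finite variances,
σ²_P = σ²_A + σ²_E. Selection retains a phenotype-z individual with
probability proportional to a non-negative weight W(z). One cycle is
analysed: parents → selected parents → offspring. Under purely additive
inheritance with a zero-mean segregation density L (offspring breeding
value = midparent + L-draw), the offspring mean breeding value equals the
selected parents' mean breeding value, which is why the response

    R = (1/W̄) ∬ y p₀(y) W(z) f(z−y) dy dz

is the mean of the *selected genotype* law pw(y) = p₀(y)W†(y)/W̄, with
W†(y) = ∫W(z)f(z−y)dz the genotype fitness (W blurred by the environment).
The selection differential is the mean of the selected phenotype law,
S = (1/W̄)∫z q₀(z)W(z)dz with q₀ = p₀ ∗ f.

Assumptions: no dominance, no epistasis, random mating, effectively
infinite population in the analytic formulas. Excluded entirely: linkage,
mutation, drift, separate sexes, overlapping generations, multi-generation
dynamics of σ²_A or G.

## Fourier representation and the proportionality condition

With the transform convention ũ(k) = ∫e^{−ikx}u(x)dx (Gaussian N(0,σ) has
cf e^{−σ²k²/2}), Parseval's identity turns the double integrals into single
k-integrals:

    W̄ = (1/2π) ∫ W̃*(k) p̃₀(k) f̃(k) dk
    R  = (i/2πW̄) ∫ W̃*(k) p̃₀′(k) f̃(k) dk
    S  = (i/2πW̄) ∫ W̃*(k) [p̃₀(k) f̃(k)]′ dk

These are real; the engine checks the imaginary residue (< 1e-8 relative)
as a convergence diagnostic. R/S is selection-independent iff
p̃₀ f̃′ = a p̃₀′ f̃, i.e. f̃ = b p̃₀^a, giving R = S/(1+a). `check_proportionality`
fits log f̃ against log p̃₀ by least squares on a k-grid chosen so both cfs
stay above 1e-8, declaring the condition satisfied when the maximum
log-residual is below 1e-6. A cf that vanishes or goes negative on the grid
(two-point genotype: cos) is reported as unsatisfied with a reason rather
than raising — such laws genuinely cannot satisfy the condition.

Exchanging the roles of p₀ and W in the same computation yields the
alternative equation: for W = N(μ, σ_W) and Gaussian f, the lags S′ = S − μ,
R′ = R − μ obey R′ = j²S′ with j² = (σ²_W + σ²_E)/σ²_W for *every* genotype
law. This identity is exercised across five structurally different genotype
families in the tests.

## Probability laws

All laws expose density (or atoms for discrete laws), cf, mean, variance,
a seeded sampler, and a `support_radius` used to truncate quadrature
domains (10 SDs for finite-variance laws). Discrete laws (point mass,
two-point) are handled by atom sums — the double integrals collapse
analytically, never by quadrature on a spike.

Symmetric α-stable laws (cf e^{−|σk|^α}, the "stretched exponentials")
are restricted to α ∈ (1, 2]: below that the mean, hence S and R, do not
exist. Note the scale convention makes α = 2 a Gaussian of variance 2σ²;
the stretched-exponential heritability formula is stated in the same
convention. For α < 2 the variance is infinite, so σ_E/σ_A is a scale
ratio, not a variance ratio, and variance-based invariants are skipped.
The density is obtained by inverting the cf with a chunked cosine
transform (2¹⁵ k-points) onto a cubic spline over |x| ≤ 60σ, switching to
the first-order tail asymptotic Γ(1+α)sin(πα/2)σ^α/(π|x|^{1+α}) beyond;
`support_radius` is where that tail falls below 1e-12 of the central peak.
Sampling uses the Chambers–Mallows–Stuck construction; the suite
cross-checks the density against scipy's independent stable pdf and the
samples against the inverted-cf CDF by a Kolmogorov–Smirnov test.

Selection weights: the Gaussian weight is unit-mass N(μ, σ_W), so reported
W̄ values are comparable across cases (the zero-variance W̄ formula is
implemented with this normalization and verified against quadrature);
weights only ever enter S, R and pw through ratios, so unnormalized custom
weights are fine and μ is always computed from the normalized weight.
Truncation selection is the indicator of z > z₀ (strict inequality; the
boundary has measure zero for continuous phenotypes); it has no normalized
mean, so the lag quantities are undefined for it, and its distributional
Fourier transform excludes it from the Fourier path.

## Numerics

* Quadrature: the inner z-integral is collapsed to closed form whenever
  possible (Gaussian×Gaussian products; truncation×Gaussian via the normal
  sf and Mills ratio) and the outer y-integral uses scipy's adaptive
  quadrature with absolute tolerance 1e-12, relative 1e-10, restricted to
  the intersection of the genotype support with the window where the
  genotype fitness is non-negligible (12 σ_W for Gaussian weights); interior
  breakpoints steer the subdivision toward the density mass. Mean fitness
  below 1e-300 raises an explicit "selection removes everyone" error.
* Fourier path: cf derivatives are analytic for Gaussian, two-point,
  mixture, point-mass and stable laws, central differences (step 1e-5)
  otherwise; k-integrals run over [−K, K] with K doubled until
  |W̃ p̃₀ f̃| < 1e-14, split at k = 0 because the stable cf derivative has a
  |k|^{α−1} kink there.
* Ratios R/S and R′/S′ are reported as undefined (None), not 0/0, when the
  denominator is below 1e-12.
* Matrix work (multivariate) uses Cholesky solves, never explicit
  inverses; singular matrices raise naming the null direction, and
  condition numbers above 1e10 warn. G and E may be singular (PSD); Ω must
  be positive definite since Ω⁻¹ defines the weight. Lande's identity is
  stated in means measured from the parental mean, the alternative identity
  in means measured from μ — the two centering conventions are kept in
  separate functions to avoid mixing them.
* Closed forms for truncation on a Gaussian-mixture genotype are derived
  here from per-component bivariate-normal algebra (within a component,
  Cov(Y, Z) = s², so E[Y|Z>z₀] shrinks the Mills-ratio shift by s²/σ²_z)
  and validated against the quadrature engine to 1e-8.

## Simulator

The individual-based cycle draws n parents from the genotype law, adds
environmental noise, applies *soft* selection (independent Bernoulli
acceptance with probability W(z)/sup W — truncation is the indicator
special case, not a fixed-quota ranking), then mates uniformly with
replacement (selfing allowed): offspring breeding value = midparent +
segregation draw, offspring phenotype adds fresh environmental noise. At
the level checked — population means under additivity — family structure
and selfing are immaterial; they would matter for variances, which are not
validated. The default segregation density is N(0, σ_A/√2)
(infinitesimal-model flavour), but only its zero mean is load-bearing and a
test swaps in a uniform density to confirm the response is unchanged.

Default population sizes follow the benchmark scenarios: 2×10⁵ parents and
offspring, which puts the standard error of S and R near 5×10⁻³ for the
named fixtures and makes 4-SE agreement a stringent check; the stochastic
tests run in seconds at that size. Every sampler takes an explicit seed;
there is no global RNG state. For the stable fixture the offspring
phenotype mean is heavy-tailed (infinite variance), so its nominal SE is an
empirical, not asymptotic, yardstick; the test compares R − h^α·S against
the combined SEs, which is the identity actually predicted.

What the simulator does *not* emulate about real data: finite-locus
genetics and Mendelian sampling correlations, linkage and assortative
mating, measurement error distinct from environmental variance, and
selection on survival rather than reproduction. Passing tests therefore
show the analytic identities hold for the idealized additive model, not
that any particular organism satisfies the model's assumptions.

## Known limitations

* Everything is one generation; iterating cycles with a frozen genotype law
  ignores the change in σ²_A that selection causes (the alternative
  equation's j² is, by construction, immune to that drift, which is its
  point).
* Truncation selection on an α-stable genotype is supported by the generic
  quadrature but slow (the integrand is not localized); the supported fast
  paths cover the cases with Gaussian selection or finite-variance laws.
* The proportionality fit requires strictly positive cfs; laws satisfying
  the condition only piecewise are reported as unsatisfied.
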