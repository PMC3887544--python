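# selresp

Exact selection-response relations for additive quantitative traits.

## The problem

Breeders and evolutionary biologists predict the response to one round of
selection with the breeder's equation **R = h²S**, where S is the selection
differential (mean phenotype of the selected parents), R the response (mean
phenotype of their offspring) and h² = σ²_A/(σ²_A + σ²_E) the heritability.
That proportionality is exact only when the *breeding-value* distribution is
normal — an unobservable assumption that selection itself destroys, and that
fails outright for crossed breeds or admixed populations.

For a trait Z = Y + ξ (breeding value plus symmetric zero-mean environmental
noise), S and R are functionals of three ingredients — the genotype law
p₀(y), the environment kernel f, and the selection weight W(z):

    W̄ = ∬ p₀(y) W(z) f(z−y) dy dz
    S  = (1/W̄) ∬ z p₀(y) W(z) f(z−y) dy dz
    R  = (1/W̄) ∬ y p₀(y) W(z) f(z−y) dy dz

In Fourier space (convention ũ(k) = ∫e^{−ikx}u(x)dx) these become single
integrals, and R ∝ S for *every* selection function exactly when
f̃(k) = b·p̃₀(k)^a, giving the universal slope R/S = 1/(1+a): h² for normal
laws, σ_A^α/(σ_A^α + σ_E^α) for symmetric stable ("stretched-exponential")
laws.

Because p₀ and W enter the double integrals symmetrically, the same argument
applied to a **Gaussian selection function** N(μ, σ_W) yields an exact linear
law that needs *no* assumption about the genotype: writing the lags
S′ = S − μ and R′ = R − μ relative to the selection optimum,

    R′ = j² S′,   j² = (σ²_W + σ²_E)/σ²_W,

for any breeding-value distribution whatsoever — the *alternative breeder's
equation*. Both relations generalize to multiple traits: Lande's equation
Δz̄ = GP⁻¹S and its alternative R′ = (Ω + E)Ω⁻¹S′, whose linear map is free
of the G matrix.

The package provides, as independent cross-checking routes:

* `distributions` — genotype laws (Gaussian, point-mass, two-point,
  Gaussian mixtures, symmetric α-stable), environment kernels and selection
  weights, with densities, characteristic functions and seeded samplers;
* `response_engine` — W̄, S, R (and the lags) by adaptive double quadrature
  and, independently, by the Fourier-space expressions; the proportionality
  condition test; truncation-threshold scans;
* `closed_forms` — every exact special case (zero genetic variance,
  Gaussian, two-point, Gaussian-mixture-under-truncation), used as fast
  paths and oracles;
* `multivariate` — Lande and alternative-Lande predictions, exact Gaussian
  algebra and Monte-Carlo verification;
* `simulator` — an individual-based selection–reproduction cycle (soft
  selection, random mating, zero-mean segregation density), the stochastic
  oracle for everything above;
* `cli` — the `selresp` command (`predict`, `simulate`, `scan-truncation`,
  `check-condition`, `multivariate`, `reproduce`).

## Worked example

The benchmark two-point genotype: breeding values ±2 with probability 1/2
(a cross of two pure lines), environment sd 3, Gaussian selection centred at
μ = 1 with width 1 — so h² = 4/13 ≈ 0.308 and j² = 10:

```sh
$ selresp predict --fixture fig3
W_bar   0.100222455579
S       0.939475064045
R       0.39475064045
mu      1
S_prime -0.060524935955
R_prime -0.60524935955
ratio_RS        0.420182137406
ratio_lag       10
h2      0.307692307692
breeder_residual        0.105681389974
j2      10
alternative_residual    -2.22044604925e-16
```

The realized heritability R/S = 0.420 is nowhere near h² = 0.308 — the
classical equation misses the response by `breeder_residual` ≈ 0.106 — while
the lag ratio R′/S′ is exactly j² = 10 (residual at machine precision), as
the alternative equation predicts for *any* genotype distribution.

The same model in the simulator (2×10⁵ individuals) recovers S and R within
Monte-Carlo error:

```sh
$ selresp simulate --fixture fig3 --seed 2 | tail -2
S       se_S    R       se_R    ratio_RS        ratio_lag
0.939337026587  0.00431749537691        0.405766011142  0.00804669667696        0.431970634242  9.79566208877
```

`selresp reproduce fig2` / `fig3` write the TSV tables behind the two
benchmark figures: the truncation scan where R/S drifts away from h² = 1/2
for a double-Gaussian genotype, and the deviation of both equations across
selection optima (the alternative one is zero to 1e-8 everywhere).

## Scope

One round of selection on purely additive traits: no dominance, epistasis,
linkage or mutation, and no multi-generation dynamics of the genetic
variance (h² and the G matrix are treated as given for the cycle being
analysed). See `docs/methods.md` for model details, numerical choices and
limitations.
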