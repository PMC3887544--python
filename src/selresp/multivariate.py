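"""Selection on multiple traits: Lande's equation and its alternative.

For trait vectors z = y + e with genotype covariance G, environment
covariance E and phenotype covariance P = G + E, and a Gaussian selection
function W(z) ∝ exp(-(z-μ)ᵀΩ⁻¹(z-μ)/2):

* Lande's (multivariate breeder's) equation
  ``z̄1 - z̄0 = G P⁻¹ (z̄w - z̄0)`` requires a Gaussian genotype;
* the alternative equation
  ``z̄1 - μ = (Ω + E) Ω⁻¹ (z̄w - μ)`` requires Gaussian selection and
  environment but holds for *any* genotype law, and its linear map is free
  of G.

Both identities hold simultaneously in the all-Gaussian model, whose means
are available in closed form (:func:`gaussian_multivariate_outcome`); a
rejection-sampling Monte-Carlo check (:func:`mc_multivariate_check`)
verifies either identity for arbitrary genotype samplers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg

__all__ = [
    "GaussianModelSpec",
    "MCReport",
    "lande_prediction",
    "alternative_lande_prediction",
    "gaussian_multivariate_outcome",
    "mc_multivariate_check",
    "two_point_trait_sampler",
]

_SYM_TOL = 1e-12
_COND_WARN = 1e10


def _check_symmetric(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if np.max(np.abs(M - M.T)) > _SYM_TOL * max(1.0, np.max(np.abs(M))):
        raise ValueError(f"{name} must be symmetric")
    return 0.5 * (M + M.T)


def _solve_spd(M: np.ndarray, b: np.ndarray, name: str) -> np.ndarray:
    """Solve M x = b for symmetric M via factorization (never an explicit
    inverse); errors on a singular matrix naming the null direction."""
    vals, vecs = np.linalg.eigh(M)
    if vals[-1] <= 0 or vals[0] <= 1e-14 * vals[-1]:
        null = vecs[:, 0]
        raise np.linalg.LinAlgError(
            f"{name} is singular along direction {np.round(null, 6).tolist()}"
        )
    if vals[-1] / vals[0] > _COND_WARN:
        warnings.warn(
            f"{name} is ill-conditioned (cond ~ {vals[-1] / vals[0]:.2e})",
            RuntimeWarning,
        )
    c, low = linalg.cho_factor(M)
    return linalg.cho_solve((c, low), b)


@dataclass
class GaussianModelSpec:
    """Covariance matrices and means of a multivariate selection model.

    ``G`` and ``E`` may be positive-semidefinite (no genetic variance /
    no environmental noise along some direction); ``Omega`` must be
    positive-definite.
    """

    G: np.ndarray
    E: np.ndarray
    Omega: np.ndarray
    mu: np.ndarray
    mean0: np.ndarray = None

    def __post_init__(self):
        self.G = _check_symmetric(self.G, "G")
        self.E = _check_symmetric(self.E, "E")
        self.Omega = _check_symmetric(self.Omega, "Omega")
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        n = self.G.shape[0]
        if self.mean0 is None:
            self.mean0 = np.zeros(n)
        self.mean0 = np.asarray(self.mean0, dtype=float).ravel()
        if not (self.E.shape[0] == self.Omega.shape[0] == n == self.mu.size == self.mean0.size):
            raise ValueError("dimension mismatch among G, E, Omega, mu, mean0")
        for M, name, strict in ((self.G, "G", False), (self.E, "E", False), (self.Omega, "Omega", True)):
            vals = np.linalg.eigvalsh(M)
            if strict and vals[0] <= 0:
                raise ValueError(f"{name} must be positive definite")
            if not strict and vals[0] < -1e-12 * max(1.0, vals[-1]):
                raise ValueError(f"{name} must be positive semidefinite")

    @property
    def P(self) -> np.ndarray:
        """Phenotype covariance P = G + E."""
        return self.G + self.E

    @property
    def n_traits(self) -> int:
        return self.G.shape[0]


def lande_prediction(spec: GaussianModelSpec, z_bar_w: np.ndarray) -> np.ndarray:
    """Lande's equation: predicted progeny mean
    ``z̄1 = z̄0 + G P⁻¹ (z̄w - z̄0)`` (means measured from the parental
    mean z̄0 = spec.mean0).  Exact only for a Gaussian genotype."""
    s = np.asarray(z_bar_w, dtype=float) - spec.mean0
    return spec.mean0 + spec.G @ _solve_spd(spec.P, s, "P")


def alternative_lande_prediction(spec: GaussianModelSpec, z_bar_w: np.ndarray) -> np.ndarray:
    """Alternative vectorial equation: predicted progeny mean
    ``z̄1 = μ + (Ω + E) Ω⁻¹ (z̄w - μ)`` (lags measured from the selection
    optimum μ).  Exact for any genotype law; the map does not involve G."""
    s_prime = np.asarray(z_bar_w, dtype=float) - spec.mu
    return spec.mu + (spec.Omega + spec.E) @ _solve_spd(spec.Omega, s_prime, "Omega")


def gaussian_multivariate_outcome(spec: GaussianModelSpec):
    """Exact (z̄w, z̄1) of the all-Gaussian model by linear-Gaussian algebra.

    The selected-phenotype mean is the posterior mean of the product
    N(mean0, P) × W, and the selected-genotype (= progeny) mean that of
    N(mean0, G) × W† with W†(y) Gaussian of covariance Ω + E:

        z̄w = mean0 + P (P + Ω)⁻¹ (μ - mean0)
        z̄1 = mean0 + G (G + Ω + E)⁻¹ (μ - mean0)

    These satisfy Lande's and the alternative identities simultaneously.
    """
    d = spec.mu - spec.mean0
    z_bar_w = spec.mean0 + spec.P @ _solve_spd(spec.P + spec.Omega, d, "P + Omega")
    z_bar_1 = spec.mean0 + spec.G @ _solve_spd(
        spec.G + spec.Omega + spec.E, d, "G + Omega + E"
    )
    return z_bar_w, z_bar_1


def two_point_trait_sampler(sigmas, mean0=None) -> Callable:
    """Sampler of independent per-trait two-point breeding values
    (mean0_i ± sigma_i with probability 1/2 each); covariance diag(sigma²).
    A deliberately non-Gaussian genotype for stress-testing Lande's
    equation."""
    sig = np.asarray(sigmas, dtype=float)
    m0 = np.zeros_like(sig) if mean0 is None else np.asarray(mean0, dtype=float)

    def sampler(n: int, rng: np.random.Generator) -> np.ndarray:
        signs = rng.choice([-1.0, 1.0], size=(n, sig.size))
        return m0 + signs * sig

    return sampler


@dataclass(frozen=True)
class MCReport:
    """Monte-Carlo verification of the two multivariate identities.

    Residuals are per-trait means over accepted individuals of
    ``y - prediction(z)``, so each has an honest standard error; an identity
    holds when every |residual| is within a few SEs of zero.
    """

    z_bar_w: np.ndarray
    z_bar_1: np.ndarray
    lande_residual: np.ndarray
    lande_se: np.ndarray
    alt_residual: np.ndarray
    alt_se: np.ndarray
    n_accepted: int
    accept_rate: float


def mc_multivariate_check(
    spec: GaussianModelSpec,
    n: int = 200_000,
    seed: int | np.random.Generator = 0,
    genotype_sampler: Callable | None = None,
) -> MCReport:
    """Simulate y ~ genotype, e ~ N(0, E), z = y + e; accept each individual
    with probability W(z)/sup W; report the selected-phenotype and
    selected-genotype means and the residual of each identity.

    ``genotype_sampler(n, rng)`` overrides the default Gaussian
    N(mean0, G) genotype; ``spec.G`` should then be the sampler's true
    covariance so the Lande map is the one a breeder would use.
    """
    if n < 1_000:
        raise ValueError("n must be at least 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = spec.n_traits
    for attempt in range(2):
        if genotype_sampler is None:
            y = rng.multivariate_normal(spec.mean0, spec.G, size=n, method="eigh")
        else:
            y = np.asarray(genotype_sampler(n, rng), dtype=float)
        e = rng.multivariate_normal(np.zeros(d), spec.E, size=n, method="eigh")
        z = y + e
        dz = z - spec.mu
        log_w = -0.5 * np.einsum("ij,ij->i", dz, _solve_spd(spec.Omega, dz.T, "Omega").T)
        keep = rng.uniform(size=n) < np.exp(log_w)
        rate = keep.mean()
        if rate >= 1e-4:
            break
        warnings.warn(
            f"acceptance rate {rate:.2e} below 1e-4; enlarging the sample",
            RuntimeWarning,
        )
        n *= 10
    else:  # pragma: no cover
        raise RuntimeError("acceptance rate remained below 1e-4")
    if keep.sum() == 0:
        raise RuntimeError("selection accepted no individuals")
    ya, za = y[keep], z[keep]
    m = ya.shape[0]
    z_bar_w = za.mean(axis=0)
    z_bar_1 = ya.mean(axis=0)

    # (G P⁻¹)ᵀ = P⁻¹ G and ((Ω+E) Ω⁻¹)ᵀ = Ω⁻¹ (Ω+E) by symmetry
    lande_map = _solve_spd(spec.P, spec.G, "P")
    lande_terms = (ya - spec.mean0) - (za - spec.mean0) @ lande_map
    alt_map = _solve_spd(spec.Omega, spec.Omega + spec.E, "Omega")
    alt_terms = (ya - spec.mu) - (za - spec.mu) @ alt_map

    return MCReport(
        z_bar_w=z_bar_w,
        z_bar_1=z_bar_1,
        lande_residual=lande_terms.mean(axis=0),
        lande_se=lande_terms.std(axis=0, ddof=1) / math.sqrt(m),
        alt_residual=alt_terms.mean(axis=0),
        alt_se=alt_terms.std(axis=0, ddof=1) / math.sqrt(m),
        n_accepted=int(m),
        accept_rate=float(rate),
    )
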