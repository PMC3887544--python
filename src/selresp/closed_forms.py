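"""Closed-form selection responses for special model families.

These exact expressions serve both as fast paths and as oracles for the
numerical engines in :mod:`selresp.response_engine`:

* the classical breeder's equation ``R = h^2 S`` with
  ``h^2 = sigma_A^2 / (sigma_A^2 + sigma_E^2)``, valid when the breeding
  values and environment are both normal;
* its stretched-exponential generalization
  ``h^alpha = sigma_A^alpha / (sigma_A^alpha + sigma_E^alpha)`` for
  symmetric stable laws;
* the alternative lag equation ``R' = j^2 S'`` with
  ``j^2 = (sigma_W^2 + sigma_E^2) / sigma_W^2``, valid for a Gaussian
  selection function and Gaussian environment *regardless* of the
  genotype law;
* fully worked model families (zero genetic variance, Gaussian breeding
  values, two-point breeding values, Gaussian-mixture genotype under
  truncation selection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "ScalarConstants",
    "heritability",
    "lag_coefficient",
    "stretched_heritability",
    "gaussian_alpha",
    "breeders_prediction",
    "alternative_prediction",
    "no_variance_case",
    "gaussian_case",
    "two_point_case",
    "truncation_mixture_case",
]


def heritability(sigma_A: float, sigma_E: float) -> float:
    """h^2 = sigma_A^2 / (sigma_A^2 + sigma_E^2), the additive-genetic share
    of the phenotypic variance."""
    if sigma_A < 0 or sigma_E < 0:
        raise ValueError("standard deviations must be non-negative")
    if sigma_A == 0 and sigma_E == 0:
        raise ValueError("at least one variance component must be positive")
    return sigma_A**2 / (sigma_A**2 + sigma_E**2)


def lag_coefficient(sigma_W: float, sigma_E: float) -> float:
    """j^2 = (sigma_W^2 + sigma_E^2) / sigma_W^2 — the slope of the
    alternative equation R' = j^2 S' under Gaussian selection; >= 1 with
    equality iff there is no environmental noise.  Independent of the
    genotype law."""
    if sigma_W <= 0:
        raise ValueError("sigma_W must be positive")
    return (sigma_W**2 + sigma_E**2) / sigma_W**2


def stretched_heritability(alpha: float, sigma_A: float, sigma_E: float) -> float:
    """Realized heritability R/S = sigma_A^alpha / (sigma_A^alpha +
    sigma_E^alpha) when genotype and environment are symmetric stable with
    a common index alpha; reduces to h^2 at alpha = 2."""
    if not 0 < alpha <= 2:
        raise ValueError("alpha must lie in (0, 2]")
    if sigma_A <= 0 or sigma_E < 0:
        raise ValueError("scales must be positive (sigma_E may be zero)")
    return sigma_A**alpha / (sigma_A**alpha + sigma_E**alpha)


def gaussian_alpha(j2: float, h2: float) -> float:
    """The shrinkage factor alpha = (j^2 - 1)/(j^2 - h^2) of the all-Gaussian
    model, giving S = alpha * mu and R = alpha * h^2 * mu."""
    if j2 == h2:
        raise ValueError("degenerate model: j^2 == h^2")
    return (j2 - 1.0) / (j2 - h2)


@dataclass(frozen=True)
class ScalarConstants:
    """The scalar constants of a fully Gaussian-kernel model."""

    sigma_A: float
    sigma_E: float
    sigma_W: float

    @property
    def h2(self) -> float:
        return heritability(self.sigma_A, self.sigma_E)

    @property
    def j2(self) -> float:
        return lag_coefficient(self.sigma_W, self.sigma_E)

    @property
    def alpha_gauss(self) -> float:
        return gaussian_alpha(self.j2, self.h2)


def breeders_prediction(h2: float, S: float) -> float:
    """Classical breeder's equation: predicted response R = h^2 S."""
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    return h2 * S


def alternative_prediction(j2: float, S_prime: float) -> float:
    """Alternative equation: predicted response lag R' = j^2 S'."""
    if j2 < 1.0:
        raise ValueError("j2 must be >= 1")
    return j2 * S_prime


def no_variance_case(mu: float, sigma_W: float, sigma_E: float):
    """Zero genetic variance (point-mass genotype at 0), unit-mass Gaussian
    selection N(mu, sigma_W) and Gaussian environment N(0, sigma_E).

    Returns (Wbar, S, R).  With no genetic variance there is no response
    (R = 0), while the selected parents still shift by
    S = mu sigma_E^2 / (sigma_W^2 + sigma_E^2); the lags nevertheless obey
    R' = j^2 S' exactly.
    """
    if sigma_W <= 0 or sigma_E <= 0:
        raise ValueError("widths must be positive")
    tot = sigma_W**2 + sigma_E**2
    w_bar = math.exp(-(mu**2) / (2.0 * tot)) / math.sqrt(2.0 * math.pi * tot)
    S = mu * sigma_E**2 / tot
    return w_bar, S, 0.0


def gaussian_case(mu: float, sigma_A: float, sigma_E: float, sigma_W: float):
    """All-Gaussian model: N(0, sigma_A) breeding values, N(0, sigma_E)
    environment, unit-mass Gaussian selection N(mu, sigma_W).

    Returns (S, R) with S = alpha mu, R = alpha h^2 mu and
    alpha = (j^2 - 1)/(j^2 - h^2); both are proportional to mu, and
    (R - mu)/(S - mu) = j^2 identically.
    """
    c = ScalarConstants(sigma_A, sigma_E, sigma_W)
    a = c.alpha_gauss
    return a * mu, a * c.h2 * mu


def two_point_case(mu: float, sigma_A: float, sigma_E: float, sigma_W: float):
    """Two-point breeding values (+/- sigma_A with probability 1/2 each),
    Gaussian environment and unit-mass Gaussian selection N(mu, sigma_W).

    Returns (S, R):

        R = sigma_A tanh(sigma_A mu / (sigma_W^2 + sigma_E^2))
        S = [mu sigma_E^2 + sigma_A sigma_W^2 tanh(...)] / (sigma_W^2 + sigma_E^2)

    Here R/S != h^2 (the classical equation fails for this bimodal
    genotype) yet (R - mu)/(S - mu) = j^2 identically.
    """
    if sigma_A <= 0 or sigma_W <= 0 or sigma_E < 0:
        raise ValueError("scales must be positive")
    tot = sigma_W**2 + sigma_E**2
    t = math.tanh(sigma_A * mu / tot)
    R = sigma_A * t
    S = (mu * sigma_E**2 + sigma_A * sigma_W**2 * t) / tot
    return S, R


def truncation_mixture_case(z0, weights, means, sds, sigma_E: float):
    """Truncation selection (z > z0) on a Gaussian-mixture genotype with
    Gaussian environment: exact response via bivariate-normal algebra.

    Within component i, (Y, Z) is jointly Gaussian with Z = Y + xi, so
    Var(Z) = s_i^2 + sigma_E^2 and Cov(Y, Z) = s_i^2.  Conditioning on
    Z > z0 gives the Mills-ratio formulas

        E[Z | Z > z0] = m_i + sigma_z lambda(a_i)
        E[Y | Z > z0] = m_i + (s_i^2 / sigma_z) lambda(a_i)

    with a_i = (z0 - m_i)/sigma_z and lambda = phi / Phi-bar.  Components
    aggregate with posterior weights w_i P(Z_i > z0).  Returns
    (Wbar, S, R); raises on survival-probability underflow.
    """
    w = np.asarray(weights, dtype=float)
    m = np.asarray(means, dtype=float)
    s = np.full_like(m, float(sds)) if np.isscalar(sds) else np.asarray(sds, dtype=float)
    if sigma_E <= 0:
        raise ValueError("sigma_E must be positive")
    sz = np.sqrt(s**2 + sigma_E**2)
    a = (z0 - m) / sz
    surv = ndtr(-a)
    w_bar = float(w @ surv)
    if w_bar <= 1e-300:
        raise FloatingPointError("survival probability underflows at this z0")
    phi = np.exp(-0.5 * a * a) / math.sqrt(2.0 * math.pi)
    # w_i * surv_i * E[.|Z>z0] == w_i * (surv_i * m_i + sigma * phi(a_i))
    num_S = float(w @ (surv * m + sz * phi))
    num_R = float(w @ (surv * m + (s**2 / sz) * phi))
    return w_bar, num_S / w_bar, num_R / w_bar
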