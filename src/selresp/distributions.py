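"""Probability laws and selection (fitness) functions for additive traits.

The model is the standard additive decomposition of a quantitative trait,

    Z = Y + xi,

where ``Y`` is the breeding value (additive genetic effect) with population
density ``p0`` and ``xi`` is an independent, symmetric, zero-mean
environmental deviation with kernel ``f``.  Selection acts on the phenotype
``Z`` through a non-negative weight ``W(z)``.

All Fourier transforms follow the convention

    u~(k) = \\int exp(-i k x) u(x) dx,

so a normal law N(mu, sigma) has characteristic function
``exp(-i k mu - sigma^2 k^2 / 2)`` and convolution becomes a product of
characteristic functions.
"""

from __future__ import annotations

import abc
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, stats

__all__ = [
    "UnivariateLaw",
    "Gaussian",
    "Dirac",
    "TwoPoint",
    "GaussianMixture",
    "SymmetricStable",
    "Uniform",
    "SelectionFunction",
    "GaussianW",
    "TruncationW",
    "CustomW",
    "phenotype_density",
    "genotype_fitness",
    "selected_genotype_density",
    "AsymmetricKernelError",
    "ZeroFitnessError",
    "QuadratureError",
]


class AsymmetricKernelError(ValueError):
    """The environment kernel is not symmetric with zero mean."""


class ZeroFitnessError(ValueError):
    """Mean fitness vanished: selection annihilates the population."""


class QuadratureError(RuntimeError):
    """A numerical integral failed to converge."""


# --------------------------------------------------------------------------
# probability laws
# --------------------------------------------------------------------------


class UnivariateLaw(abc.ABC):
    """A univariate probability law.

    Subclasses provide a density (or, for purely discrete laws, ``atoms``),
    the characteristic function, first two moments, a seeded sampler, and a
    ``support_radius`` beyond which the density mass is negligible (used to
    truncate quadrature domains).
    """

    #: list of (weight, location) pairs for purely discrete laws, else None
    atoms: list[tuple[float, float]] | None = None

    @property
    @abc.abstractmethod
    def mean(self) -> float: ...

    @property
    @abc.abstractmethod
    def variance(self) -> float:
        """Variance; ``math.inf`` for heavy-tailed laws."""

    @property
    @abc.abstractmethod
    def support_radius(self) -> float: ...

    @abc.abstractmethod
    def density(self, x):
        """Probability density at ``x`` (vectorized)."""

    @abc.abstractmethod
    def cf(self, k):
        """Characteristic function ``E[exp(-i k X)]`` (vectorized, complex)."""

    @abc.abstractmethod
    def sample(self, n: int, seed) -> np.ndarray:
        """Draw ``n`` variates using an explicit seed or Generator."""

    def cf_derivative(self, k):
        """d/dk of the characteristic function.

        Analytic in subclasses where available; central differences
        otherwise (step 1e-5).
        """
        h = 1e-5
        return (self.cf(np.asarray(k) + h) - self.cf(np.asarray(k) - h)) / (2 * h)

    def is_discrete(self) -> bool:
        return self.atoms is not None


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class Gaussian(UnivariateLaw):
    """Normal law N(mean, sd)."""

    def __init__(self, mean: float = 0.0, sd: float = 1.0):
        if sd <= 0:
            raise ValueError("sd must be positive")
        self._mean = float(mean)
        self.sd = float(sd)

    @property
    def mean(self):
        return self._mean

    @property
    def variance(self):
        return self.sd**2

    @property
    def support_radius(self):
        return 10.0 * self.sd

    def density(self, x):
        z = (np.asarray(x, dtype=float) - self._mean) / self.sd
        return np.exp(-0.5 * z * z) / (math.sqrt(2 * math.pi) * self.sd)

    def cf(self, k):
        k = np.asarray(k, dtype=float)
        return np.exp(-1j * k * self._mean - 0.5 * self.sd**2 * k**2)

    def cf_derivative(self, k):
        k = np.asarray(k, dtype=float)
        return (-1j * self._mean - self.sd**2 * k) * self.cf(k)

    def sample(self, n, seed):
        return _rng(seed).normal(self._mean, self.sd, size=n)

    def __repr__(self):
        return f"Gaussian(mean={self._mean}, sd={self.sd})"


class Dirac(UnivariateLaw):
    """Point mass at ``point`` (zero genetic variance when used as p0)."""

    def __init__(self, point: float = 0.0):
        self.point = float(point)
        self.atoms = [(1.0, self.point)]

    @property
    def mean(self):
        return self.point

    @property
    def variance(self):
        return 0.0

    @property
    def support_radius(self):
        return 0.0

    def density(self, x):
        raise ValueError("Dirac law has no density; use its atoms")

    def cf(self, k):
        return np.exp(-1j * np.asarray(k, dtype=float) * self.point)

    def cf_derivative(self, k):
        return -1j * self.point * self.cf(k)

    def sample(self, n, seed):
        return np.full(n, self.point)

    def __repr__(self):
        return f"Dirac({self.point})"


class TwoPoint(UnivariateLaw):
    """Symmetric two-point law: mass 1/2 at mean +/- sigma_A.

    Mean ``mean`` and variance ``sigma_A**2`` exactly; models a parental
    population concentrated around two breeding values (e.g. a cross of two
    pure breeds).
    """

    def __init__(self, sigma_A: float, mean: float = 0.0):
        if sigma_A <= 0:
            raise ValueError("sigma_A must be positive")
        self.sigma_A = float(sigma_A)
        self._mean = float(mean)
        self.atoms = [(0.5, self._mean - self.sigma_A), (0.5, self._mean + self.sigma_A)]

    @property
    def mean(self):
        return self._mean

    @property
    def variance(self):
        return self.sigma_A**2

    @property
    def support_radius(self):
        return self.sigma_A

    def density(self, x):
        raise ValueError("TwoPoint law has no density; use its atoms")

    def cf(self, k):
        k = np.asarray(k, dtype=float)
        return np.exp(-1j * k * self._mean) * np.cos(self.sigma_A * k)

    def cf_derivative(self, k):
        k = np.asarray(k, dtype=float)
        e = np.exp(-1j * k * self._mean)
        return e * (-1j * self._mean * np.cos(self.sigma_A * k) - self.sigma_A * np.sin(self.sigma_A * k))

    def sample(self, n, seed):
        signs = _rng(seed).choice([-1.0, 1.0], size=n)
        return self._mean + self.sigma_A * signs

    def __repr__(self):
        return f"TwoPoint(sigma_A={self.sigma_A}, mean={self._mean})"


class GaussianMixture(UnivariateLaw):
    """Finite mixture of normals, e.g. the double-Gaussian
    p0(y) = (N(m, s; y) + N(-m, s; y)) / 2 describing a cross of two breeds.
    """

    def __init__(self, weights: Sequence[float], means: Sequence[float], sds):
        w = np.asarray(weights, dtype=float)
        m = np.asarray(means, dtype=float)
        if np.isscalar(sds):
            s = np.full_like(m, float(sds))
        else:
            s = np.asarray(sds, dtype=float)
        if w.shape != m.shape or s.shape != m.shape:
            raise ValueError("weights, means, sds must have equal length")
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, rel_tol=1e-12):
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(s <= 0):
            raise ValueError("component sds must be positive")
        self.weights, self.means, self.sds = w, m, s

    @classmethod
    def double(cls, m: float, s: float) -> "GaussianMixture":
        """The symmetric double Gaussian with components at +/- m, width s;
        variance m**2 + s**2."""
        return cls([0.5, 0.5], [m, -m], s)

    @property
    def mean(self):
        return float(self.weights @ self.means)

    @property
    def variance(self):
        mu = self.mean
        return float(self.weights @ (self.sds**2 + self.means**2) - mu**2)

    @property
    def support_radius(self):
        mu = self.mean
        return float(np.max(np.abs(self.means - mu) + 10.0 * self.sds))

    def density(self, x):
        x = np.asarray(x, dtype=float)[..., None]
        comp = np.exp(-0.5 * ((x - self.means) / self.sds) ** 2) / (
            math.sqrt(2 * math.pi) * self.sds
        )
        return np.squeeze(comp @ self.weights)

    def cf(self, k):
        k = np.asarray(k, dtype=float)[..., None]
        comp = np.exp(-1j * k * self.means - 0.5 * self.sds**2 * k**2)
        return np.squeeze(comp @ self.weights.astype(complex))

    def cf_derivative(self, k):
        k = np.asarray(k, dtype=float)[..., None]
        comp = np.exp(-1j * k * self.means - 0.5 * self.sds**2 * k**2)
        dcomp = (-1j * self.means - self.sds**2 * k) * comp
        return np.squeeze(dcomp @ self.weights.astype(complex))

    def sample(self, n, seed):
        rng = _rng(seed)
        idx = rng.choice(len(self.weights), size=n, p=self.weights)
        return rng.normal(self.means[idx], self.sds[idx])

    def __repr__(self):
        return (
            f"GaussianMixture(weights={self.weights.tolist()}, "
            f"means={self.means.tolist()}, sds={self.sds.tolist()})"
        )


class Uniform(UnivariateLaw):
    """Uniform law on [mean - half_width, mean + half_width]."""

    def __init__(self, mean: float = 0.0, half_width: float = 1.0):
        if half_width <= 0:
            raise ValueError("half_width must be positive")
        self._mean = float(mean)
        self.half_width = float(half_width)

    @property
    def mean(self):
        return self._mean

    @property
    def variance(self):
        return self.half_width**2 / 3.0

    @property
    def support_radius(self):
        return self.half_width

    def density(self, x):
        x = np.asarray(x, dtype=float)
        inside = np.abs(x - self._mean) <= self.half_width
        return np.where(inside, 1.0 / (2 * self.half_width), 0.0)

    def cf(self, k):
        k = np.asarray(k, dtype=float)
        return np.exp(-1j * k * self._mean) * np.sinc(k * self.half_width / math.pi)

    def sample(self, n, seed):
        return _rng(seed).uniform(
            self._mean - self.half_width, self._mean + self.half_width, size=n
        )

    def __repr__(self):
        return f"Uniform(mean={self._mean}, half_width={self.half_width})"


class SymmetricStable(UnivariateLaw):
    """Symmetric alpha-stable law with characteristic function
    exp(-|scale * k|**alpha), alpha in (1, 2].

    These are the "stretched-exponential" laws: the only symmetric laws whose
    characteristic function is a stretched exponential of |k|.  At alpha = 2
    the law is N(0, sqrt(2)*scale) (variance ``2*scale**2`` under this scale
    convention).  For alpha < 2 the variance is infinite but the mean exists
    for alpha > 1, so selection differentials and responses remain defined.

    The density has no closed form for general alpha; it is evaluated by
    numerically inverting the characteristic function onto a cached grid,
    with the first-order tail asymptotic
    p(x) ~ Gamma(1+alpha) sin(pi alpha / 2) scale^alpha / (pi |x|^(1+alpha))
    beyond the grid.  Sampling uses the Chambers-Mallows-Stuck construction.
    """

    #: grid parameters for the numerical inversion
    _N_K = 2**15
    _N_X = 2**13
    _X_OVER_SCALE = 60.0

    def __init__(self, alpha: float, scale: float = 1.0, mean: float = 0.0):
        if not (1.0 < alpha <= 2.0):
            raise ValueError("alpha must lie in (1, 2] so the mean exists")
        if scale <= 0:
            raise ValueError("scale must be positive")
        self.alpha = float(alpha)
        self.scale = float(scale)
        self._mean = float(mean)
        self._interp = None  # lazy density grid

    @property
    def mean(self):
        return self._mean

    @property
    def variance(self):
        if self.alpha == 2.0:
            return 2.0 * self.scale**2
        return math.inf

    @property
    def support_radius(self):
        # radius where the (tail-asymptotic) density falls below 1e-12 of
        # the central peak
        if self.alpha == 2.0:  # Gaussian tails, no power-law asymptotic
            return 10.0 * math.sqrt(2) * self.scale
        peak = self._peak_density()
        c_tail = (
            math.gamma(1 + self.alpha)
            * math.sin(math.pi * self.alpha / 2)
            * self.scale**self.alpha
            / math.pi
        )
        return (c_tail / (1e-12 * peak)) ** (1.0 / (1.0 + self.alpha))

    def _peak_density(self) -> float:
        # p(0) = (1/pi) \int_0^inf exp(-(scale k)^alpha) dk
        return math.gamma(1 + 1 / self.alpha) / (math.pi * self.scale)

    def _tail_density(self, x_abs):
        c = (
            math.gamma(1 + self.alpha)
            * math.sin(math.pi * self.alpha / 2)
            * self.scale**self.alpha
            / math.pi
        )
        return c / x_abs ** (1.0 + self.alpha)

    def _build_grid(self):
        # cos-transform inversion: p(x) = (1/pi) \int_0^K cos(kx) e^{-(sk)^a} dk,
        # evaluated in x-chunks to bound the outer-product memory
        from scipy.interpolate import CubicSpline

        x_max = self._X_OVER_SCALE * self.scale
        k_max = (37.0) ** (1.0 / self.alpha) / self.scale  # e^{-37} ~ 8e-17
        k = np.linspace(0.0, k_max, self._N_K)
        phi = np.exp(-((self.scale * k) ** self.alpha))
        x = np.linspace(0.0, x_max, self._N_X)
        dens = np.empty_like(x)
        for i in range(0, x.size, 256):
            blk = x[i : i + 256]
            dens[i : i + 256] = np.trapezoid(
                np.cos(np.outer(blk, k)) * phi, k, axis=1
            )
        dens = np.maximum(dens / math.pi, 0.0)
        self._interp = (x[-1], CubicSpline(x, dens, extrapolate=False))

    def density(self, x):
        if self._interp is None:
            self._build_grid()
        x_max, spline = self._interp
        u = np.abs(np.asarray(x, dtype=float) - self._mean)
        near = np.minimum(u, x_max)
        out = np.maximum(spline(near), 0.0)
        return np.where(u > x_max, self._tail_density(np.maximum(u, x_max)), out)

    def cf(self, k):
        k = np.asarray(k, dtype=float)
        return np.exp(-1j * k * self._mean - np.abs(self.scale * k) ** self.alpha)

    def cf_derivative(self, k):
        k = np.asarray(k, dtype=float)
        mag = -self.alpha * self.scale**self.alpha * np.sign(k) * np.abs(k) ** (
            self.alpha - 1.0
        )
        return (mag - 1j * self._mean) * self.cf(k)

    def sample(self, n, seed):
        # Chambers-Mallows-Stuck, symmetric case (beta = 0)
        rng = _rng(seed)
        a = self.alpha
        if a == 2.0:
            return self._mean + rng.normal(0.0, math.sqrt(2) * self.scale, size=n)
        u = rng.uniform(-math.pi / 2, math.pi / 2, size=n)
        e = rng.exponential(1.0, size=n)
        x = (
            np.sin(a * u)
            / np.cos(u) ** (1.0 / a)
            * (np.cos((1.0 - a) * u) / e) ** ((1.0 - a) / a)
        )
        return self._mean + self.scale * x

    def __repr__(self):
        return f"SymmetricStable(alpha={self.alpha}, scale={self.scale}, mean={self._mean})"


# --------------------------------------------------------------------------
# selection functions
# --------------------------------------------------------------------------


class SelectionFunction(abc.ABC):
    """A non-negative selection weight W(z): the proportion of phenotype-z
    individuals retained for reproduction.

    ``mu`` is the mean of the normalized weight when the weight is
    integrable, ``None`` otherwise (truncation selection).  ``sup`` bounds
    the weight from above (used for rejection sampling).  ``ft`` is the
    Fourier transform of the weight when available in closed form or by
    quadrature; ``None`` when the transform is distributional (truncation).
    """

    mu: float | None = None

    @abc.abstractmethod
    def weight(self, z): ...

    @property
    @abc.abstractmethod
    def sup(self) -> float: ...

    def ft(self, k):
        """Fourier transform int exp(-ikz) W(z) dz, or raise if unavailable."""
        raise NotImplementedError(
            f"{type(self).__name__} has no integrable Fourier transform"
        )

    @property
    def has_ft(self) -> bool:
        return True

    def shifted(self, c: float) -> "SelectionFunction":
        """The weight translated by ``c``: z -> W(z - c)."""
        raise NotImplementedError


class GaussianW(SelectionFunction):
    """Unit-mass Gaussian selection weight N(mu, sigma_w; z) — the standard
    model of stabilizing / goal-directed selection around an optimum mu."""

    def __init__(self, mu: float, sigma_w: float):
        if sigma_w <= 0:
            raise ValueError("sigma_w must be positive")
        self.mu = float(mu)
        self.sigma_w = float(sigma_w)

    def weight(self, z):
        u = (np.asarray(z, dtype=float) - self.mu) / self.sigma_w
        return np.exp(-0.5 * u * u) / (math.sqrt(2 * math.pi) * self.sigma_w)

    @property
    def sup(self):
        return 1.0 / (math.sqrt(2 * math.pi) * self.sigma_w)

    def ft(self, k):
        k = np.asarray(k, dtype=float)
        return np.exp(-1j * k * self.mu - 0.5 * self.sigma_w**2 * k**2)

    def shifted(self, c):
        return GaussianW(self.mu + c, self.sigma_w)

    def __repr__(self):
        return f"GaussianW(mu={self.mu}, sigma_w={self.sigma_w})"


class TruncationW(SelectionFunction):
    """Truncation selection: keep all and only phenotypes z > z0.

    The weight is not integrable over the real line, so the normalized mean
    ``mu`` is undefined (None) and the lag quantities S', R' do not apply.
    """

    mu = None

    def __init__(self, z0: float):
        self.z0 = float(z0)

    def weight(self, z):
        return (np.asarray(z, dtype=float) > self.z0).astype(float)

    @property
    def sup(self):
        return 1.0

    @property
    def has_ft(self) -> bool:
        return False

    def shifted(self, c):
        return TruncationW(self.z0 + c)

    def __repr__(self):
        return f"TruncationW(z0={self.z0})"


class CustomW(SelectionFunction):
    """Arbitrary non-negative selection weight given as a callable.

    ``sup_bound`` must bound the weight (rejection sampling); ``support``
    is the interval outside which the weight is negligible, used for
    quadrature and the numerical Fourier transform.  ``integrable`` declares
    whether the total mass is finite, in which case ``mu`` is computed from
    the normalized weight.
    """

    def __init__(
        self,
        fn: Callable[[np.ndarray], np.ndarray],
        sup_bound: float,
        support: tuple[float, float],
        integrable: bool = True,
    ):
        if sup_bound <= 0:
            raise ValueError("sup_bound must be positive")
        self.fn = fn
        self._sup = float(sup_bound)
        self.support = (float(support[0]), float(support[1]))
        self.integrable = bool(integrable)
        self.mu = self._compute_mu() if integrable else None

    def _compute_mu(self) -> float:
        lo, hi = self.support
        mass, _ = integrate.quad(lambda z: float(self.fn(np.asarray(z))), lo, hi, limit=200)
        if mass <= 0:
            raise ZeroFitnessError("custom selection weight has zero mass")
        first, _ = integrate.quad(
            lambda z: z * float(self.fn(np.asarray(z))), lo, hi, limit=200
        )
        return first / mass

    def weight(self, z):
        z = np.asarray(z, dtype=float)
        w = np.asarray(self.fn(z), dtype=float)
        return w

    @property
    def sup(self):
        return self._sup

    @property
    def has_ft(self) -> bool:
        return self.integrable

    def ft(self, k):
        if not self.integrable:
            return super().ft(k)
        lo, hi = self.support
        k = np.atleast_1d(np.asarray(k, dtype=float))
        out = np.empty(k.shape, dtype=complex)
        for i, ki in enumerate(k):
            re, _ = integrate.quad(
                lambda z: math.cos(ki * z) * float(self.fn(np.asarray(z))),
                lo, hi, limit=200,
            )
            im, _ = integrate.quad(
                lambda z: -math.sin(ki * z) * float(self.fn(np.asarray(z))),
                lo, hi, limit=200,
            )
            out[i] = re + 1j * im
        return out if out.size > 1 else out[0]

    def shifted(self, c):
        fn = self.fn
        return CustomW(
            lambda z, _fn=fn, _c=c: _fn(np.asarray(z) - _c),
            self._sup,
            (self.support[0] + c, self.support[1] + c),
            self.integrable,
        )

    def __repr__(self):
        return f"CustomW(support={self.support}, sup={self._sup})"


# --------------------------------------------------------------------------
# derived densities
# --------------------------------------------------------------------------

_SYMMETRY_TOL = 1e-8


def check_environment_kernel(f: UnivariateLaw) -> None:
    """Validate that the environment kernel is symmetric with zero mean.

    A symmetric zero-mean law has a real characteristic function; the check
    probes the imaginary part of cf on a k-grid and the declared mean.
    """
    if abs(f.mean) > _SYMMETRY_TOL:
        raise AsymmetricKernelError(
            f"environment kernel must have zero mean, got {f.mean}"
        )
    scale = max(math.sqrt(f.variance), 1e-3) if math.isfinite(f.variance) else 1.0
    k = np.linspace(0.1, 3.0, 7) / scale
    if np.max(np.abs(np.imag(f.cf(k)))) > 1e-6:
        raise AsymmetricKernelError("environment kernel must be symmetric")


class ConvolutionLaw(UnivariateLaw):
    """The law of the sum of two independent variables (phenotype law
    q0 = p0 * f).  Means add; variances add when both are finite; the
    characteristic function is the product."""

    def __init__(self, a: UnivariateLaw, b: UnivariateLaw):
        self.a, self.b = a, b
        if a.is_discrete() and b.is_discrete():
            self.atoms = [
                (wa * wb, xa + xb) for wa, xa in a.atoms for wb, xb in b.atoms
            ]

    @property
    def mean(self):
        return self.a.mean + self.b.mean

    @property
    def variance(self):
        return self.a.variance + self.b.variance

    @property
    def support_radius(self):
        return self.a.support_radius + self.b.support_radius

    def density(self, z):
        z = np.asarray(z, dtype=float)
        for disc, cont in ((self.a, self.b), (self.b, self.a)):
            if disc.is_discrete():
                out = np.zeros_like(z, dtype=float)
                for w, x in disc.atoms:
                    out += w * cont.density(z - x)
                return out
        # both continuous: quadrature over the narrower component
        u, v = self.a, self.b
        if v.support_radius < u.support_radius:
            u, v = v, u

        def one(zi):
            lo = u.mean - u.support_radius
            hi = u.mean + u.support_radius
            val, _ = integrate.quad(
                lambda x: float(u.density(x)) * float(v.density(zi - x)),
                lo, hi, limit=200,
            )
            return val

        flat = np.atleast_1d(z)
        out = np.array([one(zi) for zi in flat])
        return out.reshape(z.shape) if z.shape else out[0]

    def cf(self, k):
        return self.a.cf(k) * self.b.cf(k)

    def cf_derivative(self, k):
        return self.a.cf_derivative(k) * self.b.cf(k) + self.a.cf(k) * self.b.cf_derivative(k)

    def sample(self, n, seed):
        rng = _rng(seed)
        return self.a.sample(n, rng) + self.b.sample(n, rng)

    def __repr__(self):
        return f"ConvolutionLaw({self.a!r}, {self.b!r})"


def phenotype_density(p0: UnivariateLaw, f: UnivariateLaw) -> ConvolutionLaw:
    """Phenotype law q0(z) = int p0(y) f(z - y) dy for Z = Y + xi.

    Rejects an environment kernel that is not symmetric with zero mean,
    since the additive decomposition then no longer preserves the mean.
    """
    check_environment_kernel(f)
    return ConvolutionLaw(p0, f)


def genotype_fitness(W: SelectionFunction, f: UnivariateLaw) -> Callable:
    """Genotype fitness W'(y) = int W(z) f(z - y) dz.

    The selection weight as felt by a breeding value once environmental
    noise is integrated out.  Uses closed forms for Gaussian pairs and for
    truncation against a Gaussian kernel; adaptive quadrature otherwise.
    """
    from . import response_engine  # late import to avoid a cycle

    moments = response_engine.conditional_moments(W, f)
    return lambda y: moments(y)[0]


class SelectedGenotypeLaw(UnivariateLaw):
    """Genotype law of the selected parents,
    pw(y) = p0(y) W'(y) / Wbar.

    Its mean is the response R: under purely additive inheritance with a
    zero-mean segregation density, the offspring mean breeding value (and
    hence mean phenotype) equals the selected parents' mean breeding value.
    """

    def __init__(self, p0, W, f):
        from . import response_engine

        check_environment_kernel(f)
        self.p0, self.W, self.f = p0, W, f
        self._moments = response_engine.conditional_moments(W, f)
        out = response_engine.compute_outcome(p0, f, W)
        self.w_bar = out.w_bar
        self._mean = out.R
        if p0.is_discrete():
            self.atoms = [
                (w * float(self._moments(x)[0]) / self.w_bar, x) for w, x in p0.atoms
            ]

    @property
    def mean(self):
        return self._mean

    @property
    def variance(self):
        if self.atoms is not None:
            m2 = sum(w * x**2 for w, x in self.atoms)
            return m2 - self._mean**2
        val, _ = integrate.quad(
            lambda y: (y - self._mean) ** 2 * float(self.density(y)),
            self.p0.mean - self.p0.support_radius,
            self.p0.mean + self.p0.support_radius,
            limit=200,
        )
        return val

    @property
    def support_radius(self):
        return self.p0.support_radius

    def density(self, y):
        if self.atoms is not None:
            raise ValueError("discrete selected-genotype law has no density")
        y = np.asarray(y, dtype=float)
        flat = np.atleast_1d(y)
        w_dag = np.array([float(self._moments(yi)[0]) for yi in flat])
        out = self.p0.density(flat) * w_dag / self.w_bar
        return out.reshape(y.shape) if y.shape else out[0]

    def cf(self, k):
        if self.atoms is not None:
            k = np.asarray(k, dtype=float)
            out = np.zeros(np.shape(k), dtype=complex)
            for w, x in self.atoms:
                out = out + w * np.exp(-1j * k * x)
            return out
        raise NotImplementedError("cf of a continuous selected law is not tabulated")

    def sample(self, n, seed):
        rng = _rng(seed)
        if self.atoms is not None:
            ws = np.array([w for w, _ in self.atoms])
            xs = np.array([x for _, x in self.atoms])
            idx = rng.choice(len(ws), size=n, p=ws / ws.sum())
            return xs[idx]
        # rejection against p0 with the genotype fitness as acceptance weight
        out = np.empty(0)
        sup = None
        while out.size < n:
            y = self.p0.sample(4 * n, rng)
            w = np.array([float(self._moments(yi)[0]) for yi in y])
            if sup is None:
                sup = w.max() * 1.05
            keep = rng.uniform(0, sup, size=y.size) < w
            out = np.concatenate([out, y[keep]])
        return out[:n]


def selected_genotype_density(
    p0: UnivariateLaw, W: SelectionFunction, f: UnivariateLaw
) -> SelectedGenotypeLaw:
    """Genotype law of the selected population; errors if selection
    annihilates the population (mean fitness 0)."""
    return SelectedGenotypeLaw(p0, W, f)
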