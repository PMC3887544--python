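"""Selection differential and response for one round of selection.

For a trait Z = Y + xi with breeding-value law ``p0``, symmetric zero-mean
environment kernel ``f`` and selection weight ``W``, the mean fitness, the
selection differential S (mean phenotype of the selected parents) and the
response R (mean phenotype of the progeny, equal under additivity to the
mean breeding value of the selected parents) are the double integrals

    Wbar = ∬ p0(y) W(z) f(z - y) dy dz
    S    = (1/Wbar) ∬ z p0(y) W(z) f(z - y) dy dz
    R    = (1/Wbar) ∬ y p0(y) W(z) f(z - y) dy dz.

Two independent evaluation paths are provided: nested adaptive quadrature
(:func:`compute_outcome`) and the Fourier-space forms
(:func:`compute_outcome_fourier`)

    R = (i / 2π Wbar) ∫ W~*(k) d/dk[p0~(k)] f~(k) dk
    S = (i / 2π Wbar) ∫ W~*(k) d/dk[p0~(k) f~(k)] dk,

which follow from Parseval's identity and make the proportionality
structure of R and S transparent: R and S are proportional for *every*
selection function iff f~ is a power of p0~
(:func:`check_proportionality`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import ndtr

from .distributions import (
    AsymmetricKernelError,
    CustomW,
    GaussianW,
    QuadratureError,
    SelectionFunction,
    TruncationW,
    UnivariateLaw,
    ZeroFitnessError,
    check_environment_kernel,
)

__all__ = [
    "SelectionOutcome",
    "ProportionalityReport",
    "compute_outcome",
    "compute_outcome_fourier",
    "check_proportionality",
    "truncation_scan",
    "conditional_moments",
]

_RATIO_FLOOR = 1e-12
_QUAD_OPTS = dict(epsabs=1e-12, epsrel=1e-10, limit=300)


@dataclass(frozen=True)
class SelectionOutcome:
    """Mean fitness, selection differential and response for one cycle.

    ``ratio_RS`` is the realized heritability R/S; ``mu``, ``S_prime``,
    ``R_prime`` and ``ratio_lag`` are populated only when the selection
    weight is integrable so its normalized mean exists.  Ratios are None
    (undefined) rather than 0/0 when the denominator is below 1e-12.
    """

    w_bar: float
    S: float
    R: float
    mu: float | None = None
    S_prime: float | None = None
    R_prime: float | None = None

    @property
    def ratio_RS(self) -> float | None:
        if abs(self.S) < _RATIO_FLOOR:
            return None
        return self.R / self.S

    @property
    def ratio_lag(self) -> float | None:
        if self.S_prime is None or abs(self.S_prime) < _RATIO_FLOOR:
            return None
        return self.R_prime / self.S_prime

    @classmethod
    def build(cls, w_bar: float, S: float, R: float, mu: float | None):
        if mu is None:
            return cls(w_bar, S, R)
        return cls(w_bar, S, R, mu, S - mu, R - mu)


@dataclass(frozen=True)
class ProportionalityReport:
    """Result of testing f~(k) = b * p0~(k)^a over a k-grid.

    When the condition holds, R = S / (1 + a_hat) for every selection
    function; ``slope`` is that universal ratio.
    """

    satisfied: bool
    a_hat: float | None
    b_hat: float | None
    max_residual: float | None
    reason: str = ""

    @property
    def slope(self) -> float | None:
        if not self.satisfied:
            return None
        return 1.0 / (1.0 + self.a_hat)


# --------------------------------------------------------------------------
# conditional z-moments against the environment kernel
# --------------------------------------------------------------------------


def conditional_moments(W: SelectionFunction, f: UnivariateLaw) -> Callable:
    """Return ``y -> (m0, m1)`` with

        m0(y) = ∫ W(z) f(z - y) dz       (the genotype fitness W'(y))
        m1(y) = ∫ z W(z) f(z - y) dz.

    Closed forms for the Gaussian-Gaussian and truncation-Gaussian pairs;
    atom sums for discrete kernels; adaptive quadrature otherwise.
    """
    from .distributions import Gaussian

    if isinstance(W, GaussianW) and isinstance(f, Gaussian) and f.mean == 0.0:
        sw2, se2 = W.sigma_w**2, f.sd**2
        tot = sw2 + se2
        norm = 1.0 / math.sqrt(2 * math.pi * tot)

        def gaussian_pair(y):
            y = np.asarray(y, dtype=float)
            m0 = norm * np.exp(-0.5 * (y - W.mu) ** 2 / tot)
            zeta = (W.mu * se2 + y * sw2) / tot
            return m0, m0 * zeta

        return gaussian_pair

    if isinstance(W, TruncationW) and isinstance(f, Gaussian) and f.mean == 0.0:
        se = f.sd

        def trunc_gauss(y):
            y = np.asarray(y, dtype=float)
            a = (W.z0 - y) / se
            m0 = ndtr(-a)  # P(y + xi > z0)
            phi = np.exp(-0.5 * a * a) / math.sqrt(2 * math.pi)
            return m0, y * m0 + se * phi

        return trunc_gauss

    if f.is_discrete():

        def discrete_env(y):
            y = np.asarray(y, dtype=float)
            m0 = np.zeros(np.shape(y))
            m1 = np.zeros(np.shape(y))
            for w, x in f.atoms:
                wz = W.weight(y + x)
                m0 = m0 + w * wz
                m1 = m1 + w * (y + x) * wz
            return m0, m1

        return discrete_env

    rf = f.support_radius

    def generic(y):
        y = float(np.asarray(y))
        lo, hi = y - rf, y + rf
        if isinstance(W, TruncationW):
            lo = max(lo, W.z0)
            if lo >= hi:
                return np.float64(0.0), np.float64(0.0)
        elif isinstance(W, GaussianW):
            lo = max(lo, W.mu - 12.0 * W.sigma_w)
            hi = min(hi, W.mu + 12.0 * W.sigma_w)
            if lo >= hi:
                return np.float64(0.0), np.float64(0.0)
        elif isinstance(W, CustomW):
            lo = max(lo, W.support[0])
            hi = min(hi, W.support[1])
            if lo >= hi:
                return np.float64(0.0), np.float64(0.0)
        m0, _ = integrate.quad(
            lambda z: float(W.weight(z)) * float(f.density(z - y)), lo, hi, **_QUAD_OPTS
        )
        m1, _ = integrate.quad(
            lambda z: z * float(W.weight(z)) * float(f.density(z - y)),
            lo, hi, **_QUAD_OPTS,
        )
        return np.float64(m0), np.float64(m1)

    return generic


def _selection_window(W: SelectionFunction, f: UnivariateLaw):
    """Interval of genotype values y where the genotype fitness is
    non-negligible; (None, None) entries mean unbounded."""
    rf = f.support_radius
    if isinstance(W, GaussianW):
        half = 10.0 * W.sigma_w + rf
        return W.mu - half, W.mu + half
    if isinstance(W, TruncationW):
        return W.z0 - rf, None
    if isinstance(W, CustomW):
        return W.support[0] - rf, W.support[1] + rf
    return None, None


def _expectations(p0: UnivariateLaw, moments, window) -> tuple[float, float, float]:
    """(E[m0], E[y m0], E[m1]) under p0, restricted to the window where the
    genotype fitness is non-negligible."""
    if p0.is_discrete():
        w_bar = num_r = num_s = 0.0
        for w, y in p0.atoms:
            m0, m1 = moments(y)
            w_bar += w * float(m0)
            num_r += w * y * float(m0)
            num_s += w * float(m1)
        return w_bar, num_r, num_s

    lo = p0.mean - p0.support_radius
    hi = p0.mean + p0.support_radius
    wlo, whi = window
    if wlo is not None:
        lo = max(lo, wlo)
    if whi is not None:
        hi = min(hi, whi)
    if lo >= hi:
        return 0.0, 0.0, 0.0

    # breakpoints guide the adaptive subdivision toward the density mass
    pts = sorted(
        {p for p in (p0.mean, wlo, whi) if p is not None and lo < p < hi}
    ) or None

    def iq(g):
        try:
            val, err = integrate.quad(g, lo, hi, points=pts, **_QUAD_OPTS)
        except Exception as exc:  # pragma: no cover - scipy-level failure
            raise QuadratureError(f"quadrature failed on [{lo}, {hi}]: {exc}") from exc
        if not math.isfinite(val):
            raise QuadratureError("quadrature returned a non-finite value")
        return val

    w_bar = iq(lambda y: float(p0.density(y)) * float(moments(y)[0]))
    num_r = iq(lambda y: y * float(p0.density(y)) * float(moments(y)[0]))
    num_s = iq(lambda y: float(p0.density(y)) * float(moments(y)[1]))
    return w_bar, num_r, num_s


def compute_outcome(
    p0: UnivariateLaw, f: UnivariateLaw, W: SelectionFunction
) -> SelectionOutcome:
    """Evaluate Wbar, S and R by (nested) adaptive quadrature.

    The inner z-integral against the kernel is collapsed to a closed form
    whenever one exists; the outer y-integral runs over the intersection of
    the genotype support with the window where the genotype fitness is
    non-negligible.  Raises :class:`ZeroFitnessError` when selection leaves
    no survivors and :class:`QuadratureError` on non-convergence.
    """
    check_environment_kernel(f)
    if not math.isfinite(p0.mean):
        raise ValueError("genotype law must have a finite mean")
    moments = conditional_moments(W, f)
    window = _selection_window(W, f)
    w_bar, num_r, num_s = _expectations(p0, moments, window)
    if w_bar <= 1e-300:
        raise ZeroFitnessError(
            f"mean fitness underflows ({w_bar!r}); selection removes everyone"
        )
    return SelectionOutcome.build(w_bar, num_s / w_bar, num_r / w_bar, W.mu)


# --------------------------------------------------------------------------
# Fourier path
# --------------------------------------------------------------------------


def _decay_K(p0, f, W) -> float:
    """Half-width of the k-integration interval: the product
    |W~ p0~ f~| must be below 1e-14 beyond it."""
    K = 1.0
    for _ in range(60):
        ks = np.linspace(K, 1.25 * K, 16)
        mag = np.abs(W.ft(ks)) * np.abs(p0.cf(ks) * f.cf(ks))
        if np.max(mag) < 1e-14:
            return 1.25 * K
        K *= 2.0
    raise QuadratureError("characteristic-function product does not decay")


def _complex_quad(g, K: float) -> complex:
    re, _ = integrate.quad(lambda k: g(k).real, -K, K, points=[0.0], **_QUAD_OPTS)
    im, _ = integrate.quad(lambda k: g(k).imag, -K, K, points=[0.0], **_QUAD_OPTS)
    return re + 1j * im


def compute_outcome_fourier(
    p0: UnivariateLaw, f: UnivariateLaw, W: SelectionFunction
) -> SelectionOutcome:
    """Evaluate Wbar, S and R through the Fourier-space expressions.

    Requires an integrable selection weight (truncation selection has only a
    distributional transform and is rejected).  The analytic results are
    real; the imaginary residue of each integral is checked against a 1e-8
    relative floor as a consistency diagnostic.
    """
    check_environment_kernel(f)
    if not W.has_ft:
        raise ValueError(
            f"{type(W).__name__} is unsupported in the Fourier path "
            "(no integrable Fourier transform)"
        )
    K = _decay_K(p0, f, W)
    two_pi = 2.0 * math.pi

    def wconj(k):
        return np.conj(W.ft(k))

    zw = _complex_quad(lambda k: wconj(k) * p0.cf(k) * f.cf(k), K) / two_pi
    zr = (
        _complex_quad(lambda k: wconj(k) * p0.cf_derivative(k) * f.cf(k), K)
        * 1j
        / two_pi
    )
    zs = (
        _complex_quad(
            lambda k: wconj(k)
            * (p0.cf_derivative(k) * f.cf(k) + p0.cf(k) * f.cf_derivative(k)),
            K,
        )
        * 1j
        / two_pi
    )
    w_bar = zw.real
    if w_bar <= 1e-300:
        raise ZeroFitnessError("mean fitness underflows in the Fourier path")
    scale = max(abs(zw), abs(zr), abs(zs), 1e-30)
    resid = max(abs(zw.imag), abs(zr.imag), abs(zs.imag)) / scale
    if resid > 1e-6:
        raise QuadratureError(
            f"imaginary residue {resid:.2e} exceeds tolerance; k-grid decay insufficient"
        )
    return SelectionOutcome.build(w_bar, zs.real / w_bar, zr.real / w_bar, W.mu)


# --------------------------------------------------------------------------
# proportionality condition
# --------------------------------------------------------------------------


def _cf_floor_K(law: UnivariateLaw, floor: float = 1e-8) -> float:
    """Largest K (by doubling + bisection) with |cf(K)| above the floor."""
    K = 1.0
    while abs(law.cf(K)) > floor and K < 1e8:
        K *= 2.0
    lo, hi = K / 2.0, K
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if abs(law.cf(mid)) > floor:
            lo = mid
        else:
            hi = mid
    return lo


def default_k_grid(p0: UnivariateLaw, f: UnivariateLaw, n: int = 201) -> np.ndarray:
    K = min(_cf_floor_K(p0), _cf_floor_K(f))
    return np.linspace(-K, K, n)


def check_proportionality(
    p0: UnivariateLaw, f: UnivariateLaw, k_grid: np.ndarray | None = None
) -> ProportionalityReport:
    """Test whether f~(k) = b p0~(k)^a on a k-grid — the necessary and
    sufficient condition for R and S to be proportional under *every*
    selection function, with universal slope R/S = 1/(1 + a).

    Requires both characteristic functions to be (numerically) real and
    positive on the grid; a genotype law whose cf crosses zero (e.g. the
    two-point law, cf = cos) cannot satisfy the condition and is reported
    as unsatisfied rather than raising.
    """
    if k_grid is None:
        k_grid = default_k_grid(p0, f)
    k = np.asarray(k_grid, dtype=float)
    p_vals = p0.cf(k)
    f_vals = f.cf(k)
    if np.max(np.abs(np.imag(p_vals))) > 1e-10 or np.max(np.abs(np.imag(f_vals))) > 1e-10:
        return ProportionalityReport(
            False, None, None, None, "characteristic functions are not real on the grid"
        )
    p_re, f_re = np.real(p_vals), np.real(f_vals)
    if np.min(p_re) <= 1e-300 or np.min(f_re) <= 1e-300:
        return ProportionalityReport(
            False, None, None, None,
            "characteristic function vanishes or changes sign on the grid",
        )
    lp, lf = np.log(p_re), np.log(f_re)
    design = np.column_stack([np.ones_like(lp), lp])
    coef, *_ = np.linalg.lstsq(design, lf, rcond=None)
    log_b, a = coef
    resid = float(np.max(np.abs(lf - design @ coef)))
    return ProportionalityReport(resid < 1e-6, float(a), float(math.exp(log_b)), resid)


# --------------------------------------------------------------------------
# truncation scan
# --------------------------------------------------------------------------


def truncation_scan(
    p0: UnivariateLaw, f: UnivariateLaw, z0_grid: np.ndarray
) -> pd.DataFrame:
    """One selection outcome per truncation threshold z0.

    Columns: z0, w_bar, S, R, ratio_RS, ok.  Thresholds where the mean
    fitness underflows (selection empties the population) are flagged
    ``ok = False`` with NaN values rather than raising.
    """
    rows = []
    for z0 in np.asarray(z0_grid, dtype=float):
        try:
            out = compute_outcome(p0, f, TruncationW(z0))
            rows.append(
                dict(z0=z0, w_bar=out.w_bar, S=out.S, R=out.R,
                     ratio_RS=out.ratio_RS, ok=True)
            )
        except (ZeroFitnessError, QuadratureError):
            rows.append(
                dict(z0=z0, w_bar=np.nan, S=np.nan, R=np.nan,
                     ratio_RS=np.nan, ok=False)
            )
    return pd.DataFrame(rows)
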