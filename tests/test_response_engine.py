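"""Quadrature and Fourier evaluation of Wbar, S, R; the proportionality
condition; truncation scans."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from selresp.closed_forms import heritability, lag_coefficient, two_point_case
from selresp.distributions import (
    CustomW,
    Dirac,
    Gaussian,
    GaussianMixture,
    GaussianW,
    SymmetricStable,
    TruncationW,
    TwoPoint,
    ZeroFitnessError,
)
from selresp.response_engine import (
    SelectionOutcome,
    check_proportionality,
    compute_outcome,
    compute_outcome_fourier,
    truncation_scan,
)


def neutral_weight(lo=-80.0, hi=80.0):
    return CustomW(lambda z: np.ones_like(np.asarray(z, dtype=float)), 1.0, (lo, hi))


# --------------------------------------------------------------------------
# quadrature path
# --------------------------------------------------------------------------


def test_zero_genetic_variance_has_no_response():
    out = compute_outcome(Dirac(0.0), Gaussian(0, 3), GaussianW(2.0, 1.0))
    assert out.R == 0.0
    assert out.S == pytest.approx(2.0 * 9.0 / 10.0, abs=1e-12)  # mu sE^2/(sW^2+sE^2)
    assert out.R_prime == pytest.approx(-2.0)
    assert out.S_prime == pytest.approx(-0.2)
    assert out.ratio_lag == pytest.approx(10.0, abs=1e-10)


def test_two_point_matches_tanh_closed_form():
    out = compute_outcome(TwoPoint(2.0), Gaussian(0, 3), GaussianW(1.0, 1.0))
    assert out.R == pytest.approx(2.0 * math.tanh(0.2), rel=1e-10)
    assert out.S == pytest.approx((9.0 + 2.0 * math.tanh(0.2)) / 10.0, rel=1e-10)
    assert out.ratio_lag == pytest.approx(10.0, rel=1e-10)


def test_truncated_normal_mills_ratio():
    # p0=N(0,1), f=N(0,1), truncation at 0: S is the mean of a standard
    # normal of variance 2 truncated at 0; R = h^2 S with h^2 = 1/2
    out = compute_outcome(Gaussian(0, 1), Gaussian(0, 1), TruncationW(0.0))
    s_expected = math.sqrt(2.0) * stats.norm.pdf(0) / 0.5
    assert out.S == pytest.approx(s_expected, rel=1e-10)
    assert out.R == pytest.approx(0.5 * s_expected, rel=1e-10)
    assert out.ratio_RS == pytest.approx(0.5, rel=1e-10)


def test_neutral_selection_returns_parental_mean():
    p0 = GaussianMixture([0.4, 0.6], [2.0, -1.0], 1.0)
    out = compute_outcome(p0, Gaussian(0, 1), neutral_weight())
    assert out.S == pytest.approx(p0.mean, abs=1e-9)
    assert out.R == pytest.approx(p0.mean, abs=1e-9)


def test_outcome_lag_bookkeeping():
    out = SelectionOutcome.build(0.1, S=0.9, R=0.4, mu=1.0)
    assert out.R_prime - out.R == pytest.approx(-1.0)
    assert out.S_prime - out.S == pytest.approx(-1.0)
    undef = SelectionOutcome.build(0.1, S=0.0, R=0.0, mu=None)
    assert undef.ratio_RS is None and undef.ratio_lag is None


def test_annihilating_selection_raises():
    with pytest.raises(ZeroFitnessError):
        compute_outcome(Gaussian(0, 1), Gaussian(0, 1), TruncationW(60.0))


def test_shift_equivariance():
    """Shifting genotype law and selection by c shifts S and R by c and
    leaves the lag ratio invariant."""
    c = 2.7
    base = compute_outcome(TwoPoint(2.0), Gaussian(0, 3), GaussianW(1.0, 1.0))
    shifted = compute_outcome(
        TwoPoint(2.0, mean=c), Gaussian(0, 3), GaussianW(1.0 + c, 1.0)
    )
    assert shifted.S == pytest.approx(base.S + c, rel=1e-9)
    assert shifted.R == pytest.approx(base.R + c, rel=1e-9)
    assert shifted.ratio_lag == pytest.approx(base.ratio_lag, rel=1e-9)


@pytest.mark.parametrize(
    "p0",
    [
        Gaussian(0, 2),
        TwoPoint(2.0),
        GaussianMixture.double(3.0, 2.0),
        Dirac(0.5),
        SymmetricStable(1.5, 1.0),
    ],
    ids=repr,
)
@pytest.mark.parametrize("mu", [-2.0, 1.0, 4.5])
def test_gaussian_selection_lag_ratio_is_j2_for_any_genotype(p0, mu):
    """The alternative equation: R'/S' = (sW^2+sE^2)/sW^2 regardless of the
    genotype law."""
    sigma_w, sigma_e = 1.0, 3.0
    out = compute_outcome(p0, Gaussian(0, sigma_e), GaussianW(mu, sigma_w))
    assert out.ratio_lag == pytest.approx(
        lag_coefficient(sigma_w, sigma_e), rel=1e-7
    )


@given(
    mu=st.floats(-4, 4),
    sigma_a=st.floats(0.5, 3),
    sigma_w=st.floats(0.5, 2),
    sigma_e=st.floats(0.5, 3),
)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_two_point_quadrature_equals_printed_formulas(mu, sigma_a, sigma_w, sigma_e):
    out = compute_outcome(
        TwoPoint(sigma_a), Gaussian(0, sigma_e), GaussianW(mu, sigma_w)
    )
    S, R = two_point_case(mu, sigma_a, sigma_e, sigma_w)
    assert out.S == pytest.approx(S, rel=1e-8, abs=1e-10)
    assert out.R == pytest.approx(R, rel=1e-8, abs=1e-10)


# --------------------------------------------------------------------------
# Fourier path
# --------------------------------------------------------------------------

FOURIER_CONFIGS = [
    (Gaussian(0, 2), Gaussian(0, 3), GaussianW(1.0, 1.0)),
    (Gaussian(0.5, 1.0), Gaussian(0, 0.8), GaussianW(-1.0, 1.5)),
    (TwoPoint(2.0), Gaussian(0, 3), GaussianW(1.0, 1.0)),
    (GaussianMixture.double(3.0, 2.0), Gaussian(0, math.sqrt(13)), GaussianW(2.0, 1.0)),
    (Dirac(0.0), Gaussian(0, 3), GaussianW(2.0, 1.0)),
    (SymmetricStable(1.5, 1.0), Gaussian(0, 1.0), GaussianW(1.0, 1.0)),
    (
        Gaussian(0, 1),
        Gaussian(0, 1),
        CustomW(
            lambda z: np.exp(-0.5 * (np.asarray(z) - 1.0) ** 2)
            + 0.5 * np.exp(-((np.asarray(z) + 2.0) ** 2)),
            1.5,
            (-12.0, 11.0),
        ),
    ),
]


@pytest.mark.parametrize("p0,f,W", FOURIER_CONFIGS, ids=lambda v: repr(v)[:40])
def test_fourier_path_matches_quadrature(p0, f, W):
    a = compute_outcome(p0, f, W)
    b = compute_outcome_fourier(p0, f, W)
    assert b.w_bar == pytest.approx(a.w_bar, rel=1e-8)
    assert b.S == pytest.approx(a.S, rel=1e-6, abs=1e-9)
    assert b.R == pytest.approx(a.R, rel=1e-6, abs=1e-9)


def test_fourier_matches_two_point_closed_form():
    out = compute_outcome_fourier(TwoPoint(2.0), Gaussian(0, 3), GaussianW(1.0, 1.0))
    S, R = two_point_case(1.0, 2.0, 3.0, 1.0)
    assert out.S == pytest.approx(S, rel=1e-8)
    assert out.R == pytest.approx(R, rel=1e-8)


def test_fourier_centered_neutral_case_is_zero():
    out = compute_outcome_fourier(Gaussian(0, 2), Gaussian(0, 1), neutral_weight())
    assert out.R == pytest.approx(0.0, abs=1e-9)
    assert out.S == pytest.approx(0.0, abs=1e-9)


def test_fourier_rejects_truncation_selection():
    with pytest.raises(ValueError, match="unsupported|Fourier"):
        compute_outcome_fourier(Gaussian(0, 1), Gaussian(0, 1), TruncationW(0.0))


# --------------------------------------------------------------------------
# proportionality condition
# --------------------------------------------------------------------------


def test_proportionality_gaussian_pair_gives_h2_slope():
    rep = check_proportionality(Gaussian(0, 2), Gaussian(0, 3))
    assert rep.satisfied
    assert rep.a_hat == pytest.approx(9.0 / 4.0, rel=1e-9)
    assert rep.slope == pytest.approx(heritability(2.0, 3.0), rel=1e-9)


def test_proportionality_stable_pair_gives_stretched_heritability():
    alpha = 1.5
    rep = check_proportionality(SymmetricStable(alpha, 1.0), SymmetricStable(alpha, 2.0))
    assert rep.satisfied
    assert rep.a_hat == pytest.approx(2.0**alpha, rel=1e-8)
    assert rep.slope == pytest.approx(1.0 / (1.0 + 2.0**alpha), rel=1e-8)


def test_proportionality_two_point_fails_without_exception():
    rep = check_proportionality(TwoPoint(2.0), Gaussian(0, 3))
    assert not rep.satisfied
    assert rep.reason
    assert rep.slope is None


def test_proportionality_mismatched_alpha_not_satisfied():
    rep = check_proportionality(SymmetricStable(1.5, 1.0), Gaussian(0, 1.0))
    assert not rep.satisfied


def test_satisfied_slope_predicts_quadrature_ratio_across_selections():
    """When the condition holds, R/S equals the predicted slope for
    structurally different selection functions."""
    p0, f = Gaussian(0, 2), Gaussian(0, 3)
    slope = check_proportionality(p0, f).slope
    selections = [
        GaussianW(1.0, 1.0),
        TruncationW(1.5),
        CustomW(
            lambda z: np.exp(-0.5 * (np.asarray(z) - 2.0) ** 2)
            + np.exp(-0.5 * (np.asarray(z) + 3.0) ** 2 / 0.25),
            1.1,
            (-12.0, 12.0),
        ),
    ]
    for W in selections:
        out = compute_outcome(p0, f, W)
        assert out.ratio_RS == pytest.approx(slope, rel=1e-7), repr(W)


# --------------------------------------------------------------------------
# truncation scan
# --------------------------------------------------------------------------


def test_truncation_scan_low_threshold_selects_everyone():
    p0 = Gaussian(1.0, 1.0)
    df = truncation_scan(p0, Gaussian(0, 1), np.array([-12.0]))
    row = df.iloc[0]
    assert row.ok
    assert row.S == pytest.approx(1.0, abs=1e-9)
    assert row.R == pytest.approx(1.0, abs=1e-9)
    assert row.ratio_RS == pytest.approx(1.0, abs=1e-8)


def test_truncation_scan_all_gaussian_ratio_is_h2_everywhere():
    h2 = heritability(1.0, 1.0)
    df = truncation_scan(Gaussian(0, 1), Gaussian(0, 1), np.linspace(-2, 2, 5))
    assert df.ok.all()
    assert np.allclose(df.ratio_RS, h2, rtol=1e-8)


def test_truncation_scan_double_gaussian_departs_from_h2():
    df = truncation_scan(
        GaussianMixture.double(3.0, 2.0),
        Gaussian(0, math.sqrt(13)),
        np.linspace(-8.0, 10.0, 7),
    )
    dev = np.abs(df.ratio_RS.to_numpy() - 0.5)
    assert np.max(dev) > 0.01  # realized heritability is not constant


def test_truncation_scan_flags_underflowing_rows():
    df = truncation_scan(Gaussian(0, 1), Gaussian(0, 1), np.array([0.0, 80.0]))
    assert df.ok.tolist() == [True, False]
    assert math.isnan(df.S.iloc[1])
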