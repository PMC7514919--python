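"""Pointwise transforms: closed-form values, calculus, and shape invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsigmoid import (
    GrayImage,
    TransformParams,
    analytic_derivative,
    apply_transform,
    difference_quotient_D,
    evaluate,
    fractional_logistic,
    modified_sigmoid_i2,
    q_exp,
    q_sigmoid_high,
    q_sigmoid_low,
    sigmoid_i1,
    taylor_ratio_R,
)

P = TransformParams  # shorthand


def params(q=1.0, family="auto", **kw):
    kw.setdefault("beta", 128.0)
    kw.setdefault("alpha", 30.0)
    kw.setdefault("lam", 1.0)
    return P(q=q, family=family, **kw)


# ---------------------------------------------------------------------------
# q-exponential


@pytest.mark.parametrize(
    "x, q, expected",
    [
        (0.0, 0.5, 1.0),
        (1.0, 0.5, 2.25),  # (1 + 0.5)^2
        (-3.0, 0.5, 0.0),  # cutoff: 1 + 0.5*(-3) < 0
        (1.0, 1.0, math.e),  # classical limit
    ],
)
def test_q_exp_values(x, q, expected):
    assert q_exp(x, q) == pytest.approx(expected, rel=1e-12)


def test_q_exp_rejects_bad_input():
    with pytest.raises(ValueError):
        q_exp(float("nan"), 0.5)
    with pytest.raises(ValueError):
        q_exp(1.0, -0.1)


def test_q_exp_classical_continuity():
    """exp_q approaches exp(x) as q -> 1 from either side."""
    x = np.linspace(-2, 2, 41)
    for q in (0.999, 1.001):
        assert np.allclose(q_exp(x, q), np.exp(x), rtol=5e-3)


# ---------------------------------------------------------------------------
# the four families: frozen point values


@pytest.mark.parametrize(
    "func, I, q, expected",
    [
        # direct evaluations with the closed forms
        (sigmoid_i1, 143.0, 1.0, 2.0 / (1.0 + math.exp(0.5))),
        (modified_sigmoid_i2, 158.0, 1.0, 1.0 / (1.0 + math.exp(-1.0))),
        (q_sigmoid_low, 143.0, 0.5, 2.0 / (1.0 + 1.25**2)),
        (q_sigmoid_high, 158.0, 1.5, 1.0 / (1.0 + 1.5**-2)),
        # the peak maps to exactly 1 in every family
        (sigmoid_i1, 128.0, 1.0, 1.0),
        (modified_sigmoid_i2, 128.0, 1.0, 1.0),
        (q_sigmoid_low, 128.0, 0.5, 1.0),
        (q_sigmoid_high, 128.0, 1.5, 1.0),
    ],
)
def test_family_point_values(func, I, q, expected):
    fam = {sigmoid_i1: "sigmoid", modified_sigmoid_i2: "modified_sigmoid",
           q_sigmoid_low: "qsig_low", q_sigmoid_high: "qsig_high"}[func]
    assert func(I, params(q=q, family=fam)) == pytest.approx(expected, rel=1e-12)


def test_tail_behaviour():
    p = params()
    assert sigmoid_i1(128.0 + 1e6 * 30.0, p) < 1e-12
    assert modified_sigmoid_i2(128.0 + 1e6 * 30.0, p) == pytest.approx(0.5, abs=1e-5)
    # the q > 1 bell levels off at 1/2, not 0
    assert q_sigmoid_high(128.0 + 1e5 * 30.0, params(q=1.5)) == pytest.approx(0.5, abs=1e-3)


def test_q_dispatch_at_unity():
    """Within Q_TOL of q = 1 the deformed kernels use the classical forms."""
    I = np.linspace(0, 255, 52)
    assert np.array_equal(q_sigmoid_low(I, params(q=1.0, family="qsig_low")),
                          sigmoid_i1(I, params()))
    assert np.array_equal(q_sigmoid_high(I, params(q=1.0, family="qsig_high")),
                          modified_sigmoid_i2(I, params()))


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    beta=st.floats(-50, 300),
    alpha=st.floats(0.01, 100),
    lam=st.floats(0.01, 10),
    q=st.floats(0, 3),
    d=st.floats(0, 500),
)
def test_range_peak_symmetry(beta, alpha, lam, q, d):
    """Every family maps into [0, 1], peaks at exactly 1 at beta, and is even about beta."""
    for family in ("sigmoid", "modified_sigmoid", "qsig_low", "qsig_high"):
        p = P(beta=beta, alpha=alpha, lam=lam, q=q, family=family, extend_q_range=True)
        lo, hi = evaluate(beta - d, p), evaluate(beta + d, p)
        # symmetric up to the rounding of beta +/- d itself
        assert lo == pytest.approx(hi, rel=1e-9, abs=1e-12)
        assert 0.0 <= hi <= 1.0
        assert evaluate(beta, p) == 1.0


def test_q_ordering_low_family():
    """For fixed I != beta the q < 1 bell is non-increasing in q and >= the sigmoid."""
    I = np.linspace(0, 255, 103)
    qs = [0.1, 0.3, 0.5, 0.7, 0.9, 1.0]
    prev = None
    for q in qs:
        vals = np.asarray(q_sigmoid_low(I, params(q=q, family="qsig_low")))
        if prev is not None:
            assert np.all(vals <= prev + 1e-15)
        prev = vals
    assert np.all(np.asarray(q_sigmoid_low(I, params(q=0.5, family="qsig_low")))
                  >= np.asarray(sigmoid_i1(I, params())))


def test_extended_q_ranges_are_opt_in():
    with pytest.raises(ValueError):
        P(beta=128, alpha=30, q=1.5, family="qsig_low")
    with pytest.raises(ValueError):
        P(beta=128, alpha=30, q=0.5, family="qsig_high")
    # low family beyond the cutoff: the one-sided limit of the expression is 0
    p = P(beta=128, alpha=30, lam=1.0, q=1.5, family="qsig_low", extend_q_range=True)
    far = 128.0 + 30.0 / (1.0 * 0.5) + 1.0  # base = 1 - lam (q-1) |I-beta|/alpha < 0
    assert q_sigmoid_low(far, p) == 0.0
    assert q_sigmoid_low(128.0, p) == 1.0
    # high family under q < 1: cutoff makes exp_q zero, hence output 1, near the peak
    p2 = P(beta=128, alpha=30, lam=1.0, q=0.5, family="qsig_high", extend_q_range=True)
    near = 128.0 + 30.0 * 1.0 * 0.5 / 2.0  # base = 1 - lam (1-q) alpha/|I-beta| <= 0
    assert q_sigmoid_high(near, p2) == 1.0
    assert q_sigmoid_high(128.0 + 1e5 * 30.0, p2) == pytest.approx(0.5, abs=1e-3)


def test_rejects_non_finite_intensity():
    for func in (sigmoid_i1, modified_sigmoid_i2):
        with pytest.raises(ValueError):
            func(float("inf"), params())


# ---------------------------------------------------------------------------
# derivatives


@pytest.mark.parametrize(
    "family, q",
    [("sigmoid", 1.0), ("modified_sigmoid", 1.0),
     ("qsig_low", 0.1), ("qsig_low", 0.5), ("qsig_high", 1.5), ("qsig_high", 3.0)],
)
def test_derivative_matches_central_difference(family, q):
    p = params(q=q, family=family)
    grid = np.arange(0.0, 256.0)
    grid = grid[np.abs(grid - p.beta) >= p.alpha / 10]
    h = 1e-6 * p.alpha
    fd = (np.asarray(evaluate(grid + h, p)) - np.asarray(evaluate(grid - h, p))) / (2 * h)
    an = np.asarray(analytic_derivative(grid, p))
    assert np.max(np.abs(an - fd) / np.abs(fd)) <= 1e-6


def test_derivative_one_sided_limits_at_peak():
    """Sigmoid and the q < 1 bell decay linearly at rate lam/(2 alpha), independent of q."""
    for p in (params(), params(q=0.5), params(q=0.2, lam=2.0, alpha=10.0)):
        assert analytic_derivative(p.beta, p) == pytest.approx(-p.lam / (2 * p.alpha), rel=1e-12)


def test_derivative_antisymmetry():
    p = params(q=0.5)
    assert analytic_derivative(120.0, p) == pytest.approx(-analytic_derivative(136.0, p), rel=1e-12)


def test_derivative_undefined_at_peak_for_flat_families():
    for family, q in (("modified_sigmoid", 1.0), ("qsig_high", 1.5)):
        with pytest.raises(ValueError, match="no analytic"):
            analytic_derivative(128.0, params(q=q, family=family))


# ---------------------------------------------------------------------------
# Taylor ratio and difference quotient


def test_taylor_ratio_is_one_at_peak():
    assert taylor_ratio_R(128.0, params(q=0.5)) == 1.0


def test_taylor_ratio_direct_evaluation():
    # independent evaluation of numerator (deformed bell) and denominator (Taylor line)
    num = 2.0 / (1.0 + (1.0 + 0.5 * (2.0 / 30.0)) ** 2)
    den = 1.0 - (1.0 / 60.0) * 2.0
    assert taylor_ratio_R(130.0, params(q=0.5)) == pytest.approx(num / den, rel=1e-12)


def test_taylor_ratio_monotone_in_intensity():
    I = np.linspace(128.0, 143.0, 200)
    for q in (0.1, 0.5, 0.9, 0.99):
        r = np.asarray(taylor_ratio_R(I, params(q=q)))
        assert np.all(np.diff(r) >= -1e-12)


def test_taylor_ratio_domain_errors():
    with pytest.raises(ValueError):
        taylor_ratio_R(143.0, params(q=1.5, family="qsig_high"))
    with pytest.raises(ValueError):
        taylor_ratio_R(100.0, params(q=0.5))  # I < beta
    with pytest.raises(ValueError):
        taylor_ratio_R(128.0 + 61.0, params(q=0.5))  # Taylor line non-positive


def test_difference_quotient_construction():
    p = params(q=3.0, family="qsig_high")
    I, dI = 128.0, 0.1
    expected = (q_sigmoid_high(I + dI, p) - q_sigmoid_high(I, p)) / dI
    assert difference_quotient_D(I, dI, p) == pytest.approx(expected, rel=1e-12)


def test_difference_quotient_vanishes_at_peak_for_moderate_q():
    """|D(128, dI)| shrinks toward 0 with the step for q = 1.5."""
    p = params(q=1.5, family="qsig_high")
    steps = np.logspace(-4, -1, 16)[::-1]  # 0.1 down to 1e-4
    mags = [abs(difference_quotient_D(128.0, float(s), p)) for s in steps]
    assert all(b <= a for a, b in zip(mags, mags[1:]))
    assert mags[-1] < 1e-5


def test_difference_quotient_rejects_bad_step():
    with pytest.raises(ValueError):
        difference_quotient_D(128.0, 0.0, params(q=1.5, family="qsig_high"))


# ---------------------------------------------------------------------------
# fractional logistic


def test_fractional_logistic_minimum_and_asymptote():
    assert fractional_logistic(128.0, 1.0, 1.0, 0.05, 2.0, 128.0) == pytest.approx(0.5)
    for I in (128.0 + 1e6, 128.0 - 1e6):
        assert fractional_logistic(I, 1.0, 1.0, 0.05, 2.0, 128.0) == pytest.approx(1.0, abs=1e-9)


def test_fractional_logistic_q_form_matches_classical_at_unity():
    I = np.linspace(0, 255, 64)
    classical = 1.0 / (1.0 + 2.0 * np.exp(-0.05 * (I - 128.0) ** 2))
    got = np.asarray(fractional_logistic(I, 1.0, 2.0, 0.05, 2.0, 128.0, q=1.0))
    assert np.allclose(got, classical, rtol=1e-9)


def test_fractional_logistic_validation():
    with pytest.raises(ValueError):
        fractional_logistic(0.0, 1.0, 1.0, 0.05, 3.5, 0.0)  # b out of (0.5, 3)
    with pytest.raises(ValueError):
        fractional_logistic(0.0, -1.0, 1.0, 0.05, 2.0, 0.0)
    with pytest.raises(ValueError):
        fractional_logistic(-1.0, 1.0, 1.0, 0.05, 1.5, 0.0)  # fractional power of negative


# ---------------------------------------------------------------------------
# whole-image application and containers


def test_apply_transform_basics(phantom):
    p = TransformParams(beta=1.0, alpha=0.03, lam=1.0, q=0.5)
    out = apply_transform(phantom, p)
    assert out.shape == phantom.shape and out.level_ceiling == 1.0
    assert 0.0 <= out.pixels.min() and out.pixels.max() == 1.0
    # the phantom's intensity peak is the transform's peak for beta = 1
    assert np.unravel_index(out.pixels.argmax(), out.shape) == (175, 175)

    const = GrayImage(np.full((4, 5), 0.3), 1.0)
    ones = apply_transform(const, TransformParams(beta=0.3, alpha=0.1))
    assert np.all(ones.pixels == 1.0)

    tiny = apply_transform(GrayImage(np.array([[0.5]]), 1.0), p)
    assert tiny.shape == (1, 1)

    scaled = apply_transform(const, TransformParams(beta=0.3, alpha=0.1), rescale_to_input=True)
    assert scaled.level_ceiling == const.level_ceiling


def test_gray_image_validation():
    with pytest.raises(ValueError):
        GrayImage(np.array([[0.5, float("nan")]]), 1.0)
    with pytest.raises(ValueError):
        GrayImage(np.array([[2.0]]), 1.0)  # above ceiling
    with pytest.raises(ValueError):
        GrayImage(np.zeros((2, 2, 2)), 1.0)


def test_transform_params_validation():
    for kw in (dict(alpha=0.0), dict(lam=-1.0), dict(q=-0.5), dict(family="bogus")):
        with pytest.raises(ValueError):
            P(beta=0.5, alpha=kw.pop("alpha", 0.1), lam=kw.pop("lam", 1.0),
              q=kw.pop("q", 1.0), family=kw.pop("family", "auto"))


def test_auto_family_resolution():
    assert P(beta=0, alpha=1, q=0.5).resolved_family() == "qsig_low"
    assert P(beta=0, alpha=1, q=2.0).resolved_family() == "qsig_high"
    assert P(beta=0, alpha=1, q=1.0).resolved_family() == "sigmoid"
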