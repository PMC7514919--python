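"""Bell-shaped sigmoid and q-sigmoid intensity transforms.

A region of interest with mean luminance ``beta`` and spread ``alpha`` can be
highlighted by a bell-shaped map that sends intensities near ``beta`` to 1 and
everything else toward a dark (or mid-gray) background.  Four families are
provided:

``sigmoid``
    ``I1(I) = 2 / (1 + exp(lam * |I - beta| / alpha))`` — background tends to 0.
``modified_sigmoid``
    ``I2(I) = 1 / (1 + exp(-lam * (|I - beta| / alpha)**-1))`` for ``I != beta``
    and 1 at ``beta`` — background tends to 1/2, flat (zero slope) at the peak.
``qsig_low`` / ``qsig_high``
    The same kernels with the exponential replaced by the Tsallis
    q-exponential ``exp_q(x) = [1 + (1-q) x]^(1/(1-q))`` (cutoff to 0 where the
    base is non-positive).  The entropic index ``q`` adds one degree of freedom
    that reshapes the shoulder of the bell: ``q < 1`` fattens the tail of the
    low family, ``q > 1`` sharpens the high family.  Both reduce to their
    classical counterparts as ``q -> 1``.

All transforms map into ``[0, 1]``, peak at exactly 1 at ``I = beta``, and are
symmetric about ``beta``.  Intensities may be on any scale; ``beta`` and
``alpha`` must simply be expressed on the same scale as the image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "Q_TOL",
    "FAMILIES",
    "TransformParams",
    "GrayImage",
    "q_exp",
    "sigmoid_i1",
    "modified_sigmoid_i2",
    "q_sigmoid_low",
    "q_sigmoid_high",
    "evaluate",
    "apply_transform",
    "analytic_derivative",
    "taylor_ratio_R",
    "difference_quotient_D",
    "fractional_logistic",
]

#: below this distance from q = 1 the classical closed forms are used,
#: avoiding the 1/(1-q) overflow in the deformed power
Q_TOL = 1e-9

FAMILIES = ("sigmoid", "modified_sigmoid", "qsig_low", "qsig_high", "auto")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TransformParams:
    """Parameter bundle (beta, alpha, lam, q) for a sigmoid-family transform.

    Parameters
    ----------
    beta:
        Target intensity to highlight, on the image's intensity scale.
    alpha:
        Scale (half-width) of the highlighted band, same units as ``beta``;
        must be positive.
    lam:
        Dimensionless gain controlling the decay away from ``beta``; positive.
    q:
        Entropic index, ``q >= 0``; ``q = 1`` restores the classical forms.
    family:
        One of ``sigmoid``, ``modified_sigmoid``, ``qsig_low``, ``qsig_high``
        or ``auto`` (resolve from ``q``).
    extend_q_range:
        Opt-in continuity extension allowing ``qsig_low`` with ``q > 1``
        (output 0 where the deformed base is non-positive) and ``qsig_high``
        with ``q < 1`` (cutoff convention: q-exponential 0, output 1).
    """

    beta: float
    alpha: float
    lam: float = 1.0
    q: float = 1.0
    family: str = "auto"
    extend_q_range: bool = False

    def __post_init__(self) -> None:
        for name in ("beta", "alpha", "lam", "q"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if self.q < 0:
            raise ValueError(f"q must be non-negative, got {self.q}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not self.extend_q_range:
            if self.family == "qsig_low" and self.q > 1.0 + Q_TOL:
                raise ValueError(
                    "qsig_low is intended for q <= 1; pass extend_q_range=True "
                    "to enable the continuity extension"
                )
            if self.family == "qsig_high" and self.q < 1.0 - Q_TOL:
                raise ValueError(
                    "qsig_high is intended for q >= 1; pass extend_q_range=True "
                    "to enable the cutoff-convention extension"
                )

    def resolved_family(self) -> str:
        """Resolve ``auto`` to a concrete family from the value of ``q``."""
        if self.family != "auto":
            return self.family
        if self.q < 1.0 - Q_TOL:
            return "qsig_low"
        if self.q > 1.0 + Q_TOL:
            return "qsig_high"
        return "sigmoid"

    def with_(self, **kwargs) -> "TransformParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GrayImage:
    """2-D grayscale raster with finite intensities in ``[0, level_ceiling]``."""

    pixels: np.ndarray
    level_ceiling: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.size < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("pixel values must be finite")
        if self.level_ceiling <= 0 or not np.isfinite(self.level_ceiling):
            raise ValueError(f"level_ceiling must be positive and finite, got {self.level_ceiling}")
        if arr.min() < 0 or arr.max() > self.level_ceiling:
            raise ValueError(
                f"pixel values must lie in [0, {self.level_ceiling}], "
                f"got range [{arr.min()}, {arr.max()}]"
            )
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def normalized(self) -> "GrayImage":
        """Return a copy rescaled onto ``[0, 1]`` (ceiling 1.0)."""
        if self.level_ceiling == 1.0:
            return GrayImage(self.pixels.copy(), 1.0)
        return GrayImage(self.pixels / self.level_ceiling, 1.0)


# ---------------------------------------------------------------------------
# numeric helpers


def _finite_array(I, name: str = "I") -> np.ndarray:
    arr = np.asarray(I, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def _like(out: np.ndarray, template) -> "float | np.ndarray":
    if np.ndim(template) == 0:
        return float(np.asarray(out).ravel()[0])
    return np.asarray(out)


def _qpow(base: np.ndarray, q: float) -> np.ndarray:
    """``base ** (1/(1-q))`` with the cutoff to 0 where ``base <= 0``.

    Evaluated as exp(log(base)/(1-q)); underflow clamps to 0 and overflow
    saturates at inf, which downstream ``a/(1+x)`` kernels map to 0.
    """
    base = np.asarray(base, dtype=np.float64)
    pos = base > 0.0
    safe = np.where(pos, base, 1.0)
    with np.errstate(over="ignore", under="ignore"):
        out = np.where(pos, np.exp(np.log(safe) / (1.0 - q)), 0.0)
    return out


def q_exp(x, q: float):
    """Tsallis q-exponential ``[1 + (1-q) x]^(1/(1-q))``, 0 past the cutoff.

    Recovers ``exp(x)`` for ``|q - 1| < Q_TOL``.  ``q`` must be >= 0.
    """
    arr = _finite_array(x, "x")
    if not np.isfinite(q) or q < 0:
        raise ValueError(f"q must be finite and non-negative, got {q!r}")
    if abs(q - 1.0) < Q_TOL:
        with np.errstate(over="ignore"):
            out = np.exp(arr)
    else:
        out = _qpow(1.0 + (1.0 - q) * arr, q)
    return _like(out, x)


def _scaled_distance(I, p: TransformParams) -> np.ndarray:
    # at least 1-D so that boolean-mask assignment works for scalar inputs
    arr = np.atleast_1d(_finite_array(I))
    return np.abs(arr - p.beta) / p.alpha


# ---------------------------------------------------------------------------
# the four families


def sigmoid_i1(I, p: TransformParams):
    """Classical bell sigmoid ``2 / (1 + exp(lam |I-beta| / alpha))``.

    Equals 1 at ``I = beta`` and decays to 0 in both tails.
    """
    d = _scaled_distance(I, p)
    with np.errstate(over="ignore"):
        out = 2.0 / (1.0 + np.exp(p.lam * d))
    return _like(out, I)


def modified_sigmoid_i2(I, p: TransformParams):
    """Modified sigmoid ``1 / (1 + exp(-lam (|I-beta|/alpha)**-1))``, 1 at beta.

    Flat at the peak (zero one-sided slope) and decays to 1/2 in the tails.
    """
    d = _scaled_distance(I, p)
    out = np.ones_like(d)
    nz = d > 0.0
    # exponent -lam / d -> -inf at the peak, so the branch value 1 is the limit
    out[nz] = expit(p.lam / d[nz])
    return _like(out, I)


def q_sigmoid_low(I, p: TransformParams):
    """q-deformed bell sigmoid ``2 / (1 + exp_q(lam |I-beta| / alpha))``.

    Intended for ``q < 1`` (heavier tail than the classical sigmoid; the
    deformed base is then always positive).  ``q`` within ``Q_TOL`` of 1
    dispatches to :func:`sigmoid_i1`.  ``q > 1`` requires the
    ``extend_q_range`` flag; pixels where the base ``1 + lam (1-q) |I-beta| /
    alpha`` is non-positive map to 0, the one-sided limit of the expression.
    """
    if abs(p.q - 1.0) < Q_TOL:
        return sigmoid_i1(I, p)
    if p.q > 1.0 and not p.extend_q_range:
        raise ValueError("q_sigmoid_low requires q <= 1 unless extend_q_range is set")
    d = _scaled_distance(I, p)
    base = 1.0 + p.lam * (1.0 - p.q) * d
    with np.errstate(divide="ignore"):
        out = np.where(base > 0.0, 2.0 / (1.0 + _qpow(base, p.q)), 0.0)
    return _like(out, I)


def q_sigmoid_high(I, p: TransformParams):
    """q-deformed modified sigmoid ``1 / (1 + exp_q(lam * F))``, ``F = -alpha/|I-beta|``.

    Intended for ``q > 1`` (the deformed base ``1 + lam (1-q) F`` then exceeds
    1 for every ``I != beta``).  Equals 1 at ``beta`` and tends to 1/2 as
    ``|I - beta| -> inf``.  ``q`` within ``Q_TOL`` of 1 dispatches to
    :func:`modified_sigmoid_i2`.  ``q < 1`` requires ``extend_q_range`` and
    uses the literal q-exponential cutoff: where the base is non-positive the
    q-exponential is 0 and the output is 1.
    """
    if abs(p.q - 1.0) < Q_TOL:
        return modified_sigmoid_i2(I, p)
    if p.q < 1.0 and not p.extend_q_range:
        raise ValueError("q_sigmoid_high requires q >= 1 unless extend_q_range is set")
    d = _scaled_distance(I, p)
    out = np.ones_like(d)
    nz = d > 0.0
    F = -1.0 / d[nz]
    base = 1.0 + p.lam * (1.0 - p.q) * F
    out[nz] = np.where(base > 0.0, 1.0 / (1.0 + _qpow(base, p.q)), 1.0)
    return _like(out, I)


_FAMILY_FUNCS = {
    "sigmoid": sigmoid_i1,
    "modified_sigmoid": modified_sigmoid_i2,
    "qsig_low": q_sigmoid_low,
    "qsig_high": q_sigmoid_high,
}


def evaluate(I, p: TransformParams):
    """Evaluate the resolved transform family of ``p`` at intensities ``I``."""
    return _FAMILY_FUNCS[p.resolved_family()](I, p)


def apply_transform(img: GrayImage, p: TransformParams, rescale_to_input: bool = False) -> GrayImage:
    """Apply the transform pixelwise.

    The output codomain is ``[0, 1]`` (ceiling 1.0).  With
    ``rescale_to_input=True`` the result is scaled back onto the input's
    intensity ceiling, convenient when writing integer formats.
    """
    out = evaluate(img.pixels, p)
    if rescale_to_input:
        return GrayImage(out * img.level_ceiling, img.level_ceiling)
    return GrayImage(out, 1.0)


# ---------------------------------------------------------------------------
# analytic calculus


def analytic_derivative(I, p: TransformParams):
    """Closed-form derivative dF/dI of the resolved family at ``I``.

    The closed forms hold for ``I > beta``; by the symmetry of every family
    about ``beta`` the derivative for ``I < beta`` is the sign-flipped
    expression.  At ``I = beta`` the sigmoid and qsig_low families return
    their one-sided (right) limit ``-lam / (2 alpha)``, which is independent
    of ``q``; the modified-sigmoid and qsig_high families have no analytic
    value there and raise (use :func:`difference_quotient_D` instead).
    """
    fam = p.resolved_family()
    arr = np.atleast_1d(_finite_array(I))
    sgn = np.sign(arr - p.beta)
    d = np.abs(arr - p.beta) / p.alpha
    at_peak = d == 0.0

    if fam in ("modified_sigmoid", "qsig_high") and np.any(at_peak):
        raise ValueError(
            f"{fam} has no analytic derivative at I = beta; "
            "use difference_quotient_D for a numerical study"
        )
    if fam in ("qsig_low", "qsig_high") and p.extend_q_range and (
        (fam == "qsig_low" and p.q > 1.0 + Q_TOL) or (fam == "qsig_high" and p.q < 1.0 - Q_TOL)
    ):
        raise ValueError("no closed-form derivative under the extended q range")

    out = np.empty_like(d)
    nz = ~at_peak
    dn = d[nz]
    if fam == "sigmoid":
        x = p.lam * dn
        mag = (2.0 * p.lam / p.alpha) * expit(x) * expit(-x)
    elif fam == "modified_sigmoid":
        x = p.lam / dn  # exponent magnitude; I2 = expit(x) for I != beta
        with np.errstate(under="ignore"):
            mag = (p.lam / p.alpha) * dn ** -2.0 * expit(x) * expit(-x)
    elif fam == "qsig_low":
        if abs(p.q - 1.0) < Q_TOL:
            return analytic_derivative(I, p.with_(family="sigmoid"))
        base = 1.0 + p.lam * (1.0 - p.q) * dn
        with np.errstate(over="ignore", under="ignore"):
            g = _qpow(base, p.q)
            mag = (2.0 * p.lam / p.alpha) * (1.0 + g) ** -2.0 * np.exp(
                (p.q / (1.0 - p.q)) * np.log(base)
            )
    else:  # qsig_high
        if abs(p.q - 1.0) < Q_TOL:
            return analytic_derivative(I, p.with_(family="modified_sigmoid"))
        base = 1.0 + p.lam * (1.0 - p.q) * (-1.0 / dn)
        with np.errstate(over="ignore", under="ignore"):
            g = _qpow(base, p.q)
            mag = (p.lam / p.alpha) * (1.0 + g) ** -2.0 * np.exp(
                (p.q / (1.0 - p.q)) * np.log(base)
            ) * dn ** -2.0

    out[nz] = -mag * np.where(sgn[nz] == 0.0, 1.0, sgn[nz])
    # one-sided (right) limit at the peak, q-independent (sigmoid / qsig_low)
    out[at_peak] = -p.lam / (2.0 * p.alpha)
    return _like(out, I)


def taylor_ratio_R(I, p: TransformParams):
    """Ratio of the ``q < 1`` q-sigmoid to its first-order Taylor expansion.

    ``R(I) = qsig_low(I) / (1 - (lam / (2 alpha)) (I - beta))`` for
    ``I >= beta`` where the denominator is positive.  ``R(beta) = 1``; values
    close to 1 certify the near-linear decay of the deformed bell just right
    of the peak, for any ``q`` in ``(0, 1)``.
    """
    if not (p.q < 1.0):
        raise ValueError("taylor_ratio_R is defined for q < 1")
    arr = _finite_array(I)
    if np.any(arr < p.beta):
        raise ValueError("taylor_ratio_R requires I >= beta")
    denom = 1.0 - (p.lam / (2.0 * p.alpha)) * (arr - p.beta)
    if np.any(denom <= 0.0):
        raise ValueError("first-order approximation is non-positive at this I")
    out = np.asarray(q_sigmoid_low(arr, p.with_(family="qsig_low"))) / denom
    return _like(out, I)


def difference_quotient_D(I, dI: float, p: TransformParams):
    """Forward difference quotient of the qsig_high family at ``I``, step ``dI``.

    ``D = (F(I + dI) - F(I)) / dI`` probes the slope where no closed form
    exists (notably at ``I = beta``).
    """
    if not (dI > 0.0):
        raise ValueError(f"dI must be positive, got {dI!r}")
    hp = p if p.family == "qsig_high" else p.with_(family="qsig_high")
    arr = _finite_array(I)
    out = (np.asarray(q_sigmoid_high(arr + dI, hp)) - np.asarray(q_sigmoid_high(arr, hp))) / dI
    return _like(out, I)


# ---------------------------------------------------------------------------
# fractional logistic comparison function


def fractional_logistic(I, Dmax: float, C: float, k: float, b: float, I0: float, q: float = 1.0):
    """Fractional logistic ``Dmax / (1 + C exp_q(-k (I - I0)^b))``.

    ``q = 1`` gives the classical form.  ``b = 2`` yields a symmetric well
    with a unique minimum ``Dmax / (1 + C)`` at ``I0`` and asymptote ``Dmax``;
    ``b = 1`` gives the S-shaped logistic.  Requires ``Dmax, C, k > 0`` and
    ``0.5 < b < 3.0``; for non-integer ``b`` the power ``(I - I0)^b`` is only
    defined for ``I >= I0``.
    """
    if not (Dmax > 0 and C > 0 and k > 0):
        raise ValueError("Dmax, C and k must be positive")
    if not (0.5 < b < 3.0):
        raise ValueError(f"b must lie in (0.5, 3.0), got {b!r}")
    arr = _finite_array(I)
    t = arr - I0
    if abs(b - round(b)) < 1e-12:
        tb = t ** int(round(b))
    else:
        if np.any(t < 0):
            raise ValueError("non-integer b requires I >= I0")
        tb = t ** b
    with np.errstate(over="ignore", under="ignore"):
        out = Dmax / (1.0 + C * np.asarray(q_exp(-k * tb, q)))
    return _like(out, I)
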