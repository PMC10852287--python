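"""Truncated-Gaussian integrals underlying the cavity self-consistency equations.

At a replica-symmetric steady state the abundance of a typical species is a
rectified Gaussian, ``B = max(0, (a + c*z)/b)`` with ``z ~ N(0, 1)``.  Every
moment of such a law reduces to one of the three integrals

    w_n(Delta) = int_{-Delta}^{inf} dx/sqrt(2*pi) (x + Delta)^n exp(-x^2/2),

for n in {0, 1, 2}, where Delta is the rescaled mean growth rate.  The cavity
solver evaluates these thousands of times, so the hot path uses closed forms
in terms of the standard-normal pdf/cdf:

    w_0(Delta) = Phi(Delta)
    w_1(Delta) = phi(Delta) + Delta * Phi(Delta)
    w_2(Delta) = (1 + Delta^2) * Phi(Delta) + Delta * phi(Delta)

Arguments are clipped to [-40, 40]; beyond that range the integrals are zero
or saturated to double precision and the raw formulas would needlessly
underflow/overflow intermediate terms.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr  # standard normal CDF, vectorized, no dist overhead

from .errors import UnsupportedOrderError

__all__ = ["w", "truncated_moment", "DELTA_CLIP"]

#: Clipping half-width for Delta; |Delta| > 40 is indistinguishable from the
#: limit at double precision (Phi(-40) ~ 7e-350 underflows to 0).
DELTA_CLIP = 40.0

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _phi(x):
    return _INV_SQRT_2PI * np.exp(-0.5 * x * x)


def w(n: int, delta):
    """Evaluate the truncated-Gaussian integral ``w_n(delta)``.

    Parameters
    ----------
    n : int
        Order of the integral; must be 0, 1 or 2.
    delta : float or array_like
        Rescaled mean growth rate Delta = g_eff / sigma_g_eff.  Values are
        clipped to ``[-DELTA_CLIP, DELTA_CLIP]``.

    Returns
    -------
    float or ndarray
        ``w_0`` is the survival probability (standard-normal CDF at delta),
        ``w_1`` and ``w_2`` the first and second moments of the unnormalized
        rectified unit Gaussian shifted by delta.  All are nonnegative and
        non-decreasing in delta.
    """
    if n not in (0, 1, 2):
        raise UnsupportedOrderError(
            f"truncated-Gaussian integral order must be 0, 1 or 2, got {n!r}"
        )
    d = np.clip(np.asarray(delta, dtype=float), -DELTA_CLIP, DELTA_CLIP)
    cdf = ndtr(d)
    if n == 0:
        out = cdf
    elif n == 1:
        out = _phi(d) + d * cdf
    else:
        out = (1.0 + d * d) * cdf + d * _phi(d)
    # rectify the tiny negative round-off the n>=1 forms can produce deep in
    # the left tail, where the exact value is +0
    out = np.maximum(out, 0.0)
    if np.isscalar(delta) or np.ndim(delta) == 0:
        return float(out)
    return out


def truncated_moment(j: int, a: float, b: float, c: float):
    """j-th moment of ``y = max(0, (a + c*z)/b)`` with ``z ~ N(0, 1)``.

    Equals ``(c/b)**j * w_j(a/c)``.  Requires ``b > 0`` and ``c > 0``.
    Note the zeroth moment is the survival probability Phi(a/c) and does not
    depend on b.
    """
    if b <= 0 or c <= 0:
        raise ValueError(f"truncated_moment requires b > 0 and c > 0, got b={b}, c={c}")
    return (c / b) ** j * w(j, a / c)
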