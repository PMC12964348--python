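"""Independent scalar reference implementations used as test oracles.

These are deliberately written as plain-float, loop-based transcriptions of
the published closed forms, separate from the vectorized library code
paths, so that agreement between the two routes checks the library
implementation rather than restating it.
"""

from __future__ import annotations

import math

from scipy.special import j1 as _j1
from scipy.special import sici as _sici


def rod_form_factor(q: float, length: float) -> float:
    """Neugebauer form factor of an infinitely thin rigid rod."""
    x = q * length
    si = float(_sici(x)[0])
    return 2.0 * si / x - 4.0 * math.sin(x / 2.0) ** 2 / x**2


def sphere_form_amplitude(q: float, radius: float) -> float:
    """3 (sin x - x cos x) / x^3, the orientation-free sphere amplitude."""
    x = q * radius
    if x < 1e-8:
        return 1.0
    return 3.0 * (math.sin(x) - x * math.cos(x)) / x**3


def two_sphere_intensity(q: float, radius: float, distance: float) -> float:
    """Normalized interference pattern of two equal spheres a fixed
    distance apart (orientation averaged), I(0) = 1."""
    phi = sphere_form_amplitude(q, radius)
    x = q * distance
    sinc = 1.0 if x < 1e-8 else math.sin(x) / x
    return phi * phi * (1.0 + sinc) / 2.0


# ---------------------------------------------------------------------------
# scalar wormlike chain, long-chain (excluded volume) parameterization

def _rg2_ideal(L: float, b: float) -> float:
    n = L / b
    return (L * b / 6.0) * (1.0 - 1.5 / n + 1.5 / n**2
                            - 0.75 / n**3 * (1.0 - math.exp(-2.0 * n)))


def _rg2_exv(L: float, b: float) -> float:
    n = L / b
    alpha_sq = (1.0 + (n / 3.12) ** 2 + (n / 8.67) ** 3) ** (0.176 / 3.0)
    return alpha_sq * _rg2_ideal(L, b)


def _debye(u: float) -> float:
    if u < 1e-5:
        return 1.0 - u / 3.0 + u * u / 12.0
    return 2.0 * (math.exp(-u) + u - 1.0) / (u * u)


def _correction(u: float) -> float:
    if u < 1e-3:
        return u / 2.0 - 13.0 * u * u / 45.0
    return (4.0 / 15.0 + 7.0 / (15.0 * u)
            - (11.0 / 15.0 + 7.0 / (15.0 * u)) * math.exp(-u))


def _low_q(q: float, L: float, b: float) -> float:
    n = L / b
    rg = math.sqrt(_rg2_exv(L, b))
    x = q * rg
    w = 0.5 * (1.0 + math.tanh((x - 1.523) / 0.1477))
    s_debye = _debye(x * x)
    if x > 1.0:
        nu = 0.585
        xm = x ** (-1.0 / nu)
        blend = ((1.0 - w) * s_debye
                 + w * (1.22 * xm + 0.4288 * xm**2 - 1.651 * xm**3))
    else:
        blend = (1.0 - w) * s_debye
    c_stiff = 3.06 * n ** (-0.44) if n > 10.0 else 1.0
    return blend + c_stiff * (b / L) * _correction(x * x)


def wormlike_chain_reference(q: float, L: float, b: float) -> float:
    """Scalar long-chain wormlike form factor with excluded volume.

    Valid for L > 4 b. The rod-regime coefficients are found by Cramer's
    rule from value/derivative continuity at q b = 3.1, with a five-point
    finite-difference derivative.
    """
    if L <= 4.0 * b:
        raise ValueError("reference path covers long chains only")
    q_cross = 3.1 / b
    if q <= q_cross:
        return _low_q(q, L, b)
    p1, p2 = 4.12, 4.42
    h = 1e-3 * q_cross
    y0 = _low_q(q_cross, L, b)
    # five-point stencil derivative
    deriv = (_low_q(q_cross - 2 * h, L, b) - 8 * _low_q(q_cross - h, L, b)
             + 8 * _low_q(q_cross + h, L, b)
             - _low_q(q_cross + 2 * h, L, b)) / (12 * h)
    t1 = (q_cross * b) ** (-p1)
    t2 = (q_cross * b) ** (-p2)
    rhs1 = y0 - math.pi / (q_cross * L)
    rhs2 = deriv + math.pi / (q_cross**2 * L)
    d1, d2 = -p1 * t1 / q_cross, -p2 * t2 / q_cross
    det = t1 * d2 - t2 * d1
    a1 = (rhs1 * d2 - t2 * rhs2) / det
    a2 = (t1 * rhs2 - rhs1 * d1) / det
    return (a1 * (q * b) ** (-p1) + a2 * (q * b) ** (-p2)
            + math.pi / (q * L))


def flexible_cylinder_reference(q: float, radius: float, L: float,
                                b: float) -> float:
    """Scalar flexible-cylinder form factor (chain x circular section)."""
    x = q * radius
    section = 1.0 if x < 1e-8 else (2.0 * float(_j1(x)) / x) ** 2
    return wormlike_chain_reference(q, L, b) * section
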