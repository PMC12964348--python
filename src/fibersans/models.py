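"""Scattering models: flexible cylinder + power law, multi-level unified
(Beaucage) model, random-walk ellipsoid chain, and Gaussian resolution
smearing.

Flexible cylinder
-----------------
The wormlike-chain form factor follows the Pedersen-Schurtenberger
"method 3" parameterization with excluded-volume statistics: a Debye-type
function with the excluded-volume radius of gyration at low q, blended
through a tanh switch into the asymptotic power law ``q**(-1/nu)`` with
Flory exponent nu = 0.585, plus a stiffness correction term, and crossing
over to rigid-rod behaviour ``pi/(qL)`` at high q. The two empirical
power-law coefficients of the rod regime are fixed by requiring the
intensity and its first derivative to be continuous at the crossover. A
circular cross-section of radius R multiplies the chain factor with
``[2 J1(qR) / (qR)]**2``. The chain factor is normalized to 1 at q = 0.

Unified (Beaucage) model
------------------------
Per structural level i (largest first):
``G_i exp(-q^2 Rg_i^2 / 3) + B_i exp(-q^2 Rg_{i+1}^2 / 3) (1/q_i*)^{D_i}``
with the error-function crossover ``q_i* = q [erf(q Rg_i / sqrt(6))]^{-3}``.
``Rg_{N+1}`` of the last level is 0 (no high-q cutoff). The power term is
evaluated as ``erf(..)^{3 D} * q^{-D}``, which vanishes smoothly as q -> 0.

Ellipsoid chain
---------------
N triaxial ellipsoids on a random walk with step d, in the decoupling
approximation:
``I ~ sum_i <F_i^2> + sum_{i != j} <F_i><F_j> [sin(qd)/(qd)]^{|i-j|}``,
orientation averages by Gauss-Legendre quadrature, volume-weighted
amplitudes, normalized so I(0) = scale + background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf, j1, spherical_jn

__all__ = [
    "FlexCylinderPowerlawParams",
    "BeaucageLevel",
    "BeaucageParams",
    "EllipsoidChainParams",
    "eval_power_law",
    "eval_flexible_cylinder",
    "wormlike_chain_factor",
    "cross_section_factor",
    "eval_beaucage",
    "eval_ellipsoid_chain",
    "smear_gaussian",
]


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class FlexCylinderPowerlawParams:
    """Parameters of the flexible-cylinder + power-law model.

    I(q) = alpha1 * P_flex(q; R, L_C, b_Kuhn) + alpha2 * q**(-D) + c
    """

    alpha1: float          # scale of the fiber term, 1/cm
    radius_R: float        # cross-section radius, A
    contour_L_C: float     # contour length, A
    kuhn_b: float          # Kuhn length (2x persistence length), A
    alpha2: float = 0.0    # power-law scale
    decay_D: float = 4.0   # Porod decay exponent
    background_c: float = 0.0  # flat background, 1/cm

    def __post_init__(self) -> None:
        if self.radius_R <= 0 or self.kuhn_b <= 0 or self.contour_L_C <= 0:
            raise ValueError("lengths must be > 0")
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("scales must be >= 0")
        if not 0.0 <= self.decay_D <= 5.0:
            raise ValueError("decay_D must be in [0, 5]")


@dataclass(frozen=True)
class BeaucageLevel:
    G: float    # Guinier prefactor, 1/cm
    Rg: float   # radius of gyration, A
    B: float    # power-law prefactor
    D: float    # decay exponent

    def __post_init__(self) -> None:
        if self.G < 0 or self.B < 0:
            raise ValueError("G and B must be >= 0")
        if self.Rg <= 0:
            raise ValueError("Rg must be > 0")
        if not 0.0 < self.D <= 4.5:
            raise ValueError("D must be in (0, 4.5]")


@dataclass(frozen=True)
class BeaucageParams:
    """Unified-model parameters; ``levels`` ordered largest structure first."""

    levels: tuple[BeaucageLevel, ...]
    background_c: float = 0.0

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise ValueError("need at least one level")
        rgs = [lv.Rg for lv in self.levels]
        if any(rgs[i] <= rgs[i + 1] for i in range(len(rgs) - 1)):
            raise ValueError("Rg must decrease across levels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class EllipsoidChainParams:
    """Random-walk chain of triaxial ellipsoids."""

    n_subunits: int
    semi_axes: tuple[tuple[float, float, float], ...]  # per subunit (a,b,c), A
    step_length: float   # center-to-center distance, A
    scale: float = 1.0       # forward intensity, 1/cm
    background: float = 0.0  # 1/cm

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        if len(self.semi_axes) != self.n_subunits:
            raise ValueError("need one semi-axis triple per subunit")
        for axes in self.semi_axes:
            if len(axes) != 3 or any(a <= 0 for a in axes):
                raise ValueError("semi-axes must be three positive lengths")
        if self.step_length <= 0:
            raise ValueError("step_length must be > 0")

    @classmethod
    def uniform(cls, n_subunits: int, semi_axes: Sequence[float],
                step_length: float, scale: float = 1.0,
                background: float = 0.0) -> "EllipsoidChainParams":
        """Chain of identical ellipsoids."""
        axes = tuple(float(a) for a in semi_axes)
        return cls(n_subunits=n_subunits,
                   semi_axes=tuple(axes for _ in range(n_subunits)),
                   step_length=step_length, scale=scale, background=background)


# ---------------------------------------------------------------------------
# power law

def eval_power_law(q: np.ndarray, alpha2: float, decay_D: float,
                   background_c: float = 0.0) -> np.ndarray:
    """``alpha2 * q**(-D) + c`` elementwise; q must be > 0 when alpha2 > 0."""
    q = np.asarray(q, dtype=float)
    if alpha2 == 0.0:
        return np.full_like(q, background_c)
    return alpha2 * np.power(q, -decay_D) + background_c


# ---------------------------------------------------------------------------
# wormlike chain (Pedersen-Schurtenberger method 3, excluded volume)

_NU = 0.585                      # Flory exponent for excluded-volume chains
_C1, _C2, _C3 = 1.22, 0.4288, -1.651   # asymptotic power-law coefficients
_P1_LONG, _P2_LONG = 4.12, 4.42        # rod-crossover exponents, n > 4
_QB_CROSS_LONG = 3.1                   # crossover at q*b for long chains


def _rg2_benoit_doty(L: float, b: float) -> float:
    """Benoit-Doty radius of gyration squared of an ideal wormlike chain."""
    n = L / b
    if n < 0.05:
        # series limit; the closed form cancels catastrophically as n -> 0
        return (L * b / 6.0) * n * (0.5 - 0.2 * n)
    return (L * b / 6.0) * (
        1.0 - 1.5 / n + 1.5 / n**2 - 0.75 / n**3 * (1.0 - np.exp(-2.0 * n)))


def _alpha_sq(n: float) -> float:
    """Excluded-volume expansion factor squared, alpha^2(n = L/b)."""
    return (1.0 + (n / 3.12) ** 2 + (n / 8.67) ** 3) ** (0.176 / 3.0)


def _debye(u: np.ndarray) -> np.ndarray:
    """Debye function 2(exp(-u) + u - 1)/u^2 of u = (q Rg)^2."""
    u = np.asarray(u, dtype=float)
    small = u < 1e-5
    safe = np.where(small, 1.0, u)
    full = 2.0 * (np.exp(-safe) + safe - 1.0) / safe**2
    return np.where(small, 1.0 - u / 3.0 + u**2 / 12.0, full)


def _stiffness_correction(u: np.ndarray) -> np.ndarray:
    """4/15 + 7/(15u) - (11/15 + 7/(15u)) exp(-u); -> u/2 as u -> 0."""
    u = np.asarray(u, dtype=float)
    small = u < 1e-3
    safe = np.where(small, 1.0, u)
    full = (4.0 / 15.0 + 7.0 / (15.0 * safe)
            - (11.0 / 15.0 + 7.0 / (15.0 * safe)) * np.exp(-safe))
    return np.where(small, u / 2.0 - 13.0 * u**2 / 45.0, full)


def _w_switch(x: np.ndarray) -> np.ndarray:
    """tanh switch from the Debye regime to the asymptotic power law."""
    return 0.5 * (1.0 + np.tanh((x - 1.523) / 0.1477))


def _s_exv(q: np.ndarray, rg: float) -> np.ndarray:
    """Excluded-volume chain factor: Debye/power-law tanh blend.

    Below x = q*Rg = 1 the switch weight w is < 1e-3 while the power-law
    terms diverge as x**(-3/nu); their product is < 1e-5 there but becomes
    numerically explosive at x << 1, so the power part is dropped below
    x = 1 (the blend is continuous to ~1e-6).
    """
    x = q * rg
    w = _w_switch(x)
    u = x * x
    active = x > 1.0
    safe_x = np.where(active, x, 1.0)
    xm = safe_x ** (-1.0 / _NU)
    power = _C1 * xm + _C2 * xm**2 + _C3 * xm**3
    return (1.0 - w) * _debye(u) + np.where(active, w * power, 0.0)


def _chain_low_q(q: np.ndarray, L: float, b: float) -> np.ndarray:
    """Low-q branch of the long-chain factor (below the rod crossover)."""
    n = L / b
    rg2 = _alpha_sq(n) * _rg2_benoit_doty(L, b)
    rg = np.sqrt(rg2)
    stiff_scale = 3.06 * n ** (-0.44) if n > 10.0 else 1.0
    return (_s_exv(q, rg)
            + stiff_scale * (b / L) * _stiffness_correction(q * q * rg2))


def _kholodenko(q: np.ndarray, L: float, b: float,
                n_quad: int = 96) -> np.ndarray:
    """Kholodenko wormlike-chain form factor (no excluded volume).

    Interpolates exactly between the Debye coil and the rigid rod, which
    makes it the right parameterization for short/stiff chains (L <~ 4b)
    where excluded-volume effects are negligible anyway.

    P(q) = (2/x) [I1(x) - I2(x)/x],  x = 3 L / b,
    I1 = int_0^x f(z) dz,  I2 = int_0^x z f(z) dz,
    f(z) = sinh(E z)/(E sinh z) with E = sqrt(1 - (qb/3)^2)  for qb < 3,
    f(z) = sin(F z)/(F sinh z)  with F = sqrt((qb/3)^2 - 1)  for qb > 3.
    """
    x = 3.0 * L / b
    nodes, wts = np.polynomial.legendre.leggauss(n_quad)
    z = 0.5 * x * (nodes + 1.0)
    zw = 0.5 * x * wts
    y = np.asarray(q, dtype=float) * b / 3.0
    # stable sinh ratio: sinh(Ez)/sinh(z) = exp((E-1)z) (1-exp(-2Ez))/(1-exp(-2z))
    expm2z = np.exp(-2.0 * z)
    f = np.empty((y.size, z.size))
    for i, yi in enumerate(y):
        if yi < 1.0:
            e = np.sqrt(1.0 - yi * yi)
            if e < 1e-8:
                f[i] = z / np.sinh(z)
            else:
                f[i] = (np.exp((e - 1.0) * z) * (1.0 - np.exp(-2.0 * e * z))
                        / (e * (1.0 - expm2z)))
        else:
            g = np.sqrt(max(yi * yi - 1.0, 0.0))
            if g < 1e-8:
                f[i] = z / np.sinh(z)
            else:
                f[i] = (2.0 * np.sin(g * z) * np.exp(-z)
                        / (g * (1.0 - expm2z)))
    i1 = f @ zw
    i2 = (f * z) @ zw
    return (2.0 / x) * (i1 - i2 / x)


def _rod_coefficients(L: float, b: float,
                      q_cross: float, p1: float, p2: float) -> tuple[float, float]:
    """Match a1 (qb)^-p1 + a2 (qb)^-p2 + pi/(qL) to the low-q branch.

    Value and first derivative are made continuous at the crossover, which
    pins down the two empirical coefficients.
    """
    h = 1e-4 * q_cross
    y = float(_chain_low_q(np.array([q_cross]), L, b)[0])
    yp = float((_chain_low_q(np.array([q_cross + h]), L, b)[0]
                - _chain_low_q(np.array([q_cross - h]), L, b)[0]) / (2 * h))
    t1 = (q_cross * b) ** (-p1)
    t2 = (q_cross * b) ** (-p2)
    rhs1 = y - np.pi / (q_cross * L)
    rhs2 = yp + np.pi / (q_cross**2 * L)
    # derivative rows: d/dq (qb)^-p = -p/q (qb)^-p
    det = t1 * t2 * (p1 - p2) / q_cross
    a1 = (rhs1 * (-p2 * t2 / q_cross) - t2 * rhs2) / det
    a2 = (t1 * rhs2 - rhs1 * (-p1 * t1 / q_cross)) / det
    return a1, a2


def wormlike_chain_factor(q: np.ndarray, contour_L: float,
                          kuhn_b: float) -> np.ndarray:
    """Normalized wormlike-chain form factor P(q), P(0) = 1.

    Excluded-volume statistics for long chains (L > 4b); the short-chain
    branch (without excluded volume) covers L <= 4b down to the rigid-rod
    limit.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    L, b = float(contour_L), float(kuhn_b)
    if L <= 0 or b <= 0:
        raise ValueError("contour and Kuhn lengths must be > 0")
    n = L / b
    if n <= 3.0:
        # short/stiff chains: excluded volume is negligible and the
        # Kholodenko interpolation is exact in both the rod and coil limits
        return np.clip(_kholodenko(q, L, b), 0.0, None)
    if n < 5.0:
        # cosine ramp between the parameterizations keeps the model
        # continuous in (L, b), which matters for gradient-based fitting
        t = 0.5 - 0.5 * np.cos(np.pi * (n - 3.0) / 2.0)
        return np.clip((1.0 - t) * _kholodenko(q, L, b)
                       + t * _long_chain(q, L, b), 0.0, None)
    return np.clip(_long_chain(q, L, b), 0.0, None)


def _long_chain(q: np.ndarray, L: float, b: float) -> np.ndarray:
    """Method-3 excluded-volume chain with the rod-regime crossover."""
    q_cross = _QB_CROSS_LONG / b
    out = np.empty_like(q)
    low = q <= q_cross
    out[low] = _chain_low_q(q[low], L, b)
    if np.any(~low):
        a1, a2 = _rod_coefficients(L, b, q_cross, _P1_LONG, _P2_LONG)
        qh = q[~low]
        out[~low] = (a1 * (qh * b) ** (-_P1_LONG)
                     + a2 * (qh * b) ** (-_P2_LONG) + np.pi / (qh * L))
    return out


def cross_section_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Circular cross-section factor [2 J1(qR)/(qR)]^2, -> 1 as q -> 0."""
    q = np.asarray(q, dtype=float)
    x = q * radius
    small = np.abs(x) < 1e-8
    safe = np.where(small, 1.0, x)
    val = (2.0 * j1(safe) / safe) ** 2
    return np.where(small, 1.0, val)


def eval_flexible_cylinder(q: np.ndarray,
                           params: FlexCylinderPowerlawParams) -> np.ndarray:
    """Flexible cylinder + power law + background on an arbitrary q-grid."""
    q = np.asarray(q, dtype=float)
    fiber = (params.alpha1
             * wormlike_chain_factor(q, params.contour_L_C, params.kuhn_b)
             * cross_section_factor(q, params.radius_R))
    return fiber + eval_power_law(q, params.alpha2, params.decay_D,
                                  params.background_c)


# ---------------------------------------------------------------------------
# unified (Beaucage) model

def eval_beaucage(q: np.ndarray, params: BeaucageParams) -> np.ndarray:
    """Multi-level unified model with error-function crossovers.

    The power-law term of level i is cut off at low q by the next-smaller
    level's Guinier factor ``exp(-q^2 Rg_{i+1}^2 / 3)``; the last level has
    no cutoff (Rg_{N+1} = 0).
    """
    q = np.asarray(q, dtype=float)
    out = np.full_like(q, float(params.background_c))
    levels = params.levels
    for i, lv in enumerate(levels):
        rg_next = levels[i + 1].Rg if i + 1 < len(levels) else 0.0
        out = out + lv.G * np.exp(-(q * lv.Rg) ** 2 / 3.0)
        if lv.B != 0.0:
            # (1/q*)^D = [erf(q Rg/sqrt(6))^3 / q]^D; erf^3 ~ q^3 kills the
            # q^-D divergence smoothly at low q.
            erf3 = erf(q * lv.Rg / np.sqrt(6.0)) ** 3
            with np.errstate(divide="ignore", invalid="ignore"):
                power = np.where(q > 0, (erf3 ** lv.D) * q ** (-lv.D), 0.0)
            out = out + lv.B * np.exp(-(q * rg_next) ** 2 / 3.0) * power
    return out


# ---------------------------------------------------------------------------
# random-walk ellipsoid chain

def _ellipsoid_amplitude_averages(
        q: np.ndarray, semi_axes: Sequence[tuple[float, float, float]],
        n_quad: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Volume-weighted <F> and <F^2> per subunit by Gauss-Legendre quadrature.

    Returns arrays of shape (n_subunits, len(q)). Amplitudes are normalized
    to F(0) = 1 before volume weighting.
    """
    # orientation average over one octant: t = cos(theta) in [0,1], phi in [0,pi/2]
    t_nodes, t_w = np.polynomial.legendre.leggauss(n_quad)
    t = 0.5 * (t_nodes + 1.0)
    tw = 0.5 * t_w
    p_nodes, p_w = np.polynomial.legendre.leggauss(n_quad)
    phi = 0.25 * np.pi * (p_nodes + 1.0)
    pw = 0.25 * np.pi * p_w
    sin_t = np.sqrt(1.0 - t**2)
    # direction components, shape (nt, nphi)
    ex = np.outer(sin_t, np.cos(phi))
    ey = np.outer(sin_t, np.sin(phi))
    ez = np.outer(t, np.ones_like(phi))
    weights = np.outer(tw, pw) * (2.0 / np.pi)  # integrates to 1
    f_mean = np.empty((len(semi_axes), q.size))
    f2_mean = np.empty_like(f_mean)
    for k, (a, b, c) in enumerate(semi_axes):
        r_eff = np.sqrt((a * ex) ** 2 + (b * ey) ** 2 + (c * ez) ** 2)
        u = q[:, None] * r_eff.ravel()[None, :]  # (nq, nt*nphi)
        small = np.abs(u) < 1e-8
        safe = np.where(small, 1.0, u)
        amp = np.where(small, 1.0, 3.0 * spherical_jn(1, safe) / safe)
        w = weights.ravel()
        f_mean[k] = amp @ w
        f2_mean[k] = (amp * amp) @ w
    return f_mean, f2_mean


def eval_ellipsoid_chain(q: np.ndarray, params: EllipsoidChainParams,
                         n_quad: int = 32) -> np.ndarray:
    """Random-walk ellipsoid chain in the decoupling approximation.

    Cross terms between subunits i and j carry the random-walk interference
    factor ``[sin(qd)/(qd)]**|i-j|``; I(0) = scale + background exactly.
    """
    q = np.asarray(q, dtype=float)
    f_mean, f2_mean = _ellipsoid_amplitude_averages(q, params.semi_axes,
                                                    n_quad)
    volumes = np.array([a * b * c for a, b, c in params.semi_axes])
    w = volumes / volumes.sum()
    x = q * params.step_length
    small = np.abs(x) < 1e-8
    sinc = np.where(small, 1.0 - x**2 / 6.0,
                    np.sin(np.where(small, 1.0, x)) / np.where(small, 1.0, x))
    n = params.n_subunits
    intensity = np.zeros_like(q)
    for i in range(n):
        intensity += w[i] ** 2 * f2_mean[i]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            intensity += (w[i] * w[j] * f_mean[i] * f_mean[j]
                          * sinc ** abs(i - j))
    return params.scale * intensity + params.background


# ---------------------------------------------------------------------------
# resolution smearing

def smear_gaussian(intensity: np.ndarray, q: np.ndarray,
                   dq_over_q: float, n_hermite: int = 21) -> np.ndarray:
    """Gaussian resolution smearing with sigma_q = dq_over_q * q.

    The model curve, known on the grid ``q``, is convolved at each point
    with a Gaussian of relative width ``dq_over_q`` using Gauss-Hermite
    quadrature; values between grid points are interpolated log-log and the
    ends are extended with the local power law.
    """
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if dq_over_q < 0:
        raise ValueError("dq_over_q must be >= 0")
    if dq_over_q == 0 or q.size < 3:
        return intensity.copy()
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_hermite)
    weights = weights / np.sqrt(2.0 * np.pi)

    floor = max(np.max(np.abs(intensity)) * 1e-12, 1e-300)
    shifted = intensity - intensity.min() + floor  # keep logs defined
    logq = np.log(q)
    logi = np.log(shifted)
    # local power-law slopes for extrapolation beyond the grid
    slope_lo = (logi[1] - logi[0]) / (logq[1] - logq[0])
    slope_hi = (logi[-1] - logi[-2]) / (logq[-1] - logq[-2])

    q_eval = q[:, None] * (1.0 + dq_over_q * nodes[None, :])
    q_eval = np.clip(q_eval, q[0] * 1e-3, None)
    lq = np.log(q_eval)
    li = np.interp(lq, logq, logi)
    below = lq < logq[0]
    above = lq > logq[-1]
    li = np.where(below, logi[0] + slope_lo * (lq - logq[0]), li)
    li = np.where(above, logi[-1] + slope_hi * (lq - logq[-1]), li)
    vals = np.exp(li) + (intensity.min() - floor)
    return vals @ weights
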