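"""Neutron scattering-length densities, contrasts and match points.

In a contrast-variation SANS experiment the solvent is a D2O/H2O mixture.
A component whose scattering-length density (SLD) equals the solvent's is
invisible to neutrons; the D2O volume fraction where that happens is its
*contrast match point*. Both the component SLD (through solvent-exchangeable
"labile" hydrogens) and the solvent SLD are affine in the D2O fraction, so
the match point has a closed form.

Two estimators are provided:

* :func:`match_point` — the closed-form (theoretical) match point from a
  molecular composition and mass density;
* :func:`match_point_from_series` — the experimental estimator: intensities
  of a measured contrast series are integrated over a q-window, and the
  integrated intensity (proportional to contrast squared, hence quadratic
  in the D2O fraction) is fitted with a second-degree polynomial whose
  minimum locates the match point.

SLD units are 1e-6 / Angstrom^2 throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .curves import ScatteringCurve

__all__ = [
    "MolecularComposition",
    "SolventSpec",
    "SLDValue",
    "MatchPointResult",
    "NoMatchPointError",
    "NoInteriorMinimumError",
    "parse_fraction",
    "parse_formula",
    "solvent_sld",
    "composition_sld",
    "match_point",
    "match_point_from_series",
    "excess_sld",
    "GLCNAC_ANHYDRO",
    "chitin_composition",
]

# Bound coherent neutron scattering lengths, fm (Sears, Neutron News 3 (1992) 26).
COHERENT_B_FM: dict[str, float] = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "S": 2.804,
    "P": 5.13,
    "Na": 3.63,
    "Cl": 9.577,
    "K": 3.67,
    "Ca": 4.70,
    "Mg": 5.375,
    "Fe": 9.45,
    "Cu": 7.718,
    "Zn": 5.680,
}

# Standard atomic weights, g/mol (D as the 2H isotope mass).
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "Na": 22.990,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Mg": 24.305,
    "Fe": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
}

# Liquid water densities near 25 C, g/mL.
H2O_DENSITY = 0.9970
D2O_DENSITY = 1.1044

# Avogadro constant scaled so that V[A^3] = M[g/mol] / (rho[g/mL] * N_A_SCALE).
_NA_SCALE = 0.602214076

_FM_PER_A = 1.0e-5  # 1 fm = 1e-5 Angstrom


class NoMatchPointError(ValueError):
    """Composition and solvent SLD lines are parallel: no match point."""


class NoInteriorMinimumError(ValueError):
    """The fitted quadratic has no interior minimum."""


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``"C8H13NO5"`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {pos}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        if elem not in COHERENT_B_FM:
            raise ValueError(f"no scattering length tabulated for {elem!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def parse_fraction(value: float | str) -> float:
    """Accept a fraction as 0-1 or as an explicit percentage string.

    ``0.47`` -> 0.47; ``"47%"`` -> 0.47. Bare numbers above 1 are rejected
    so that an unintended percent is never silently misread.
    """
    if isinstance(value, str):
        s = value.strip()
        if s.endswith("%"):
            return float(s[:-1]) / 100.0
        value = float(s)
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(
            f"fraction {value} outside [0, 1]; use a percent string like '47%'"
        )
    return value


@dataclass(frozen=True)
class SolventSpec:
    """D2O/H2O mixture: ``f_d2o`` is the D2O volume fraction."""

    f_d2o: float
    exchange_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_d2o <= 1.0:
            raise ValueError("f_d2o must be in [0, 1]")
        if not 0.0 <= self.exchange_fraction <= 1.0:
            raise ValueError("exchange_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SLDValue:
    """A scattering-length density, units 1e-6 / Angstrom^2."""

    sld: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sld):
            raise ValueError("SLD must be finite")

    def __float__(self) -> float:
        return float(self.sld)


@dataclass(frozen=True)
class MatchPointResult:
    """Closed-form match point; ``reachable`` is False outside [0, 1]."""

    fraction: float
    reachable: bool

    def __float__(self) -> float:
        return float(self.fraction)


@dataclass(frozen=True)
class MolecularComposition:
    """Elemental composition plus the bookkeeping needed for SLD work.

    ``element_counts`` lists atoms per monomer/molecule with hydrogen under
    ``"H"`` regardless of lability; ``labile_h_count`` of those H are
    solvent-exchangeable (N-H/O-H), and ``deuteration_fraction`` of the
    remaining non-labile H are biosynthetically replaced by D. Explicit
    ``"D"`` entries are counted as permanent deuterium.
    """

    element_counts: dict[str, float]
    labile_h_count: float = 0.0
    deuteration_fraction: float = 0.0
    mass_density: float = 1.0

    def __post_init__(self) -> None:
        for elem, n in self.element_counts.items():
            if elem not in COHERENT_B_FM:
                raise ValueError(f"no scattering length tabulated for {elem!r}")
            if n < 0:
                raise ValueError(f"negative count for {elem!r}")
        if not 0.0 <= self.deuteration_fraction <= 1.0:
            raise ValueError("deuteration_fraction must be in [0, 1]")
        if self.mass_density <= 0:
            raise ValueError("mass_density must be > 0")
        h_total = self.element_counts.get("H", 0.0)
        if not 0.0 <= self.labile_h_count <= h_total:
            raise ValueError("labile_h_count must be in [0, total H]")

    @classmethod
    def from_formula(cls, formula: str, labile_h_count: float = 0.0,
                     deuteration_fraction: float = 0.0,
                     mass_density: float = 1.0) -> "MolecularComposition":
        return cls(
            element_counts={k: float(v) for k, v in parse_formula(formula).items()},
            labile_h_count=float(labile_h_count),
            deuteration_fraction=float(deuteration_fraction),
            mass_density=float(mass_density),
        )

    @property
    def molar_mass(self) -> float:
        """g/mol, including biosynthetic deuteration (labile H counted as H)."""
        m = sum(n * ATOMIC_MASS[e] for e, n in self.element_counts.items())
        nonlabile_h = self.element_counts.get("H", 0.0) - self.labile_h_count
        m += nonlabile_h * self.deuteration_fraction * (
            ATOMIC_MASS["D"] - ATOMIC_MASS["H"])
        return m

    @property
    def molecular_volume(self) -> float:
        """Molecular volume in Angstrom^3, V = M / (rho * N_A)."""
        if self.mass_density <= 0:
            raise ValueError("undefined volume: mass_density must be > 0")
        return self.molar_mass / (self.mass_density * _NA_SCALE)

    def scattering_length_fm(self, f_d2o: float,
                             exchange_fraction: float = 1.0) -> float:
        """Total coherent scattering length, fm, in a given solvent.

        Non-labile H: a ``deuteration_fraction`` portion carries b_D. Labile
        H: a portion ``exchange_fraction * f_d2o`` has exchanged to D.
        """
        b_h, b_d = COHERENT_B_FM["H"], COHERENT_B_FM["D"]
        total = sum(n * COHERENT_B_FM[e]
                    for e, n in self.element_counts.items() if e != "H")
        h_total = self.element_counts.get("H", 0.0)
        nonlabile = h_total - self.labile_h_count
        total += nonlabile * (b_h + self.deuteration_fraction * (b_d - b_h))
        total += self.labile_h_count * (
            b_h + exchange_fraction * f_d2o * (b_d - b_h))
        return total


# The chitin monomer: the N-acetylglucosamine anhydro unit C8H13NO5 with
# three exchangeable hydrogens (two O-H, one N-H); fiber density 1.5 g/mL.
GLCNAC_ANHYDRO = "C8H13NO5"


def chitin_composition(mass_density: float = 1.5) -> MolecularComposition:
    """GlcNAc anhydro-unit composition of beta-chitin."""
    return MolecularComposition.from_formula(
        GLCNAC_ANHYDRO, labile_h_count=3, mass_density=mass_density)


def _water_sld(b_sum_fm: float, molar_mass: float, density: float) -> float:
    volume = molar_mass / (density * _NA_SCALE)
    return b_sum_fm * _FM_PER_A / volume * 1e6


#: SLD of pure H2O and pure D2O, 1e-6 / A^2.
SLD_H2O = _water_sld(2 * COHERENT_B_FM["H"] + COHERENT_B_FM["O"],
                     2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"], H2O_DENSITY)
SLD_D2O = _water_sld(2 * COHERENT_B_FM["D"] + COHERENT_B_FM["O"],
                     2 * ATOMIC_MASS["D"] + ATOMIC_MASS["O"], D2O_DENSITY)


def solvent_sld(spec: SolventSpec) -> SLDValue:
    """SLD of a D2O/H2O mixture, linear in the D2O volume fraction."""
    return SLDValue(SLD_H2O + spec.f_d2o * (SLD_D2O - SLD_H2O))


def composition_sld(comp: MolecularComposition,
                    solvent: SolventSpec) -> SLDValue:
    """SLD of a molecule in a given solvent, 1e-6 / A^2.

    The sum of scattering lengths accounts for biosynthetic deuteration of
    non-labile H and for labile H carrying the solvent-weighted scattering
    length (fraction ``exchange_fraction * f_d2o`` as D).
    """
    b_total = comp.scattering_length_fm(solvent.f_d2o,
                                        solvent.exchange_fraction)
    return SLDValue(b_total * _FM_PER_A / comp.molecular_volume * 1e6)


def excess_sld(comp: MolecularComposition, solvent: SolventSpec) -> float:
    """Excess SLD of the component over the solvent, 1e-6 / A^2."""
    return float(composition_sld(comp, solvent)) - float(solvent_sld(solvent))


def _affine_coefficients(comp: MolecularComposition,
                         exchange_fraction: float) -> tuple[float, float]:
    """(intercept, slope) of the composition SLD as a function of f_d2o."""
    s0 = float(composition_sld(comp, SolventSpec(0.0, exchange_fraction)))
    s1 = float(composition_sld(comp, SolventSpec(1.0, exchange_fraction)))
    return s0, s1 - s0


def match_point(comp: MolecularComposition,
                exchange_fraction: float = 1.0) -> MatchPointResult:
    """Closed-form contrast match point of a composition.

    Solves ``composition_sld(f) == solvent_sld(f)`` for the D2O fraction f;
    both sides are affine in f. The solution may fall outside [0, 1]
    (an unreachable match point, e.g. for perdeuterated molecules); it is
    returned as-is with ``reachable=False``.
    """
    c0, c_slope = _affine_coefficients(comp, exchange_fraction)
    s0, s_slope = SLD_H2O, SLD_D2O - SLD_H2O
    denom = c_slope - s_slope
    if abs(denom) < 1e-12 * max(abs(c_slope), abs(s_slope), 1.0):
        raise NoMatchPointError(
            "composition and solvent SLD lines are parallel: no match point")
    f = (s0 - c0) / denom
    return MatchPointResult(fraction=f, reachable=0.0 <= f <= 1.0)


def match_point_from_series(
    series: Iterable[tuple[float, ScatteringCurve]],
    q_window: tuple[float, float] = (0.03, 0.4),
) -> float:
    """Match point from a measured contrast-variation series.

    Each curve is integrated (trapezoid rule on its native q-grid) over
    ``q_window``; the integrated intensity as a function of the D2O
    fraction is fitted with a second-degree polynomial and the abscissa of
    its minimum is returned. Because the coherent intensity scales with
    contrast squared, the integrated intensity is exactly quadratic in the
    D2O fraction for an ideal series.
    """
    pairs = [(parse_fraction(f), c) for f, c in series]
    if len(pairs) < 3 or len({f for f, _ in pairs}) < 3:
        raise ValueError("need at least 3 distinct D2O fractions")
    lo, hi = q_window
    if lo >= hi:
        raise ValueError("empty q-window")
    fracs = np.array([f for f, _ in pairs])
    integrals = np.empty_like(fracs)
    for i, (_, curve) in enumerate(pairs):
        if lo < curve.q[0] or hi > curve.q[-1]:
            raise ValueError(
                f"q-window [{lo}, {hi}] outside curve range "
                f"[{curve.q[0]:g}, {curve.q[-1]:g}]")
        sub = curve.subrange(lo, hi)
        integrals[i] = np.trapezoid(sub.intensity, sub.q)
    a, b, _ = np.polyfit(fracs, integrals, 2)
    if a <= max(1e-14, 1e-10 * float(np.max(np.abs(integrals)))):
        raise NoInteriorMinimumError(
            "quadratic fit of integrated intensity has no interior minimum")
    return float(-b / (2 * a))
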