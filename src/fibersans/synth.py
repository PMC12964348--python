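"""Synthetic SANS curves and contrast-variation series.

The generator emulates pinhole-SANS curves of the kind a D11-type
instrument produces: a log-spaced q-grid over 0.0013-0.4102 1/A, Gaussian
resolution smearing from the wavelength spread, and multiplicative
Gaussian noise standing in for counting statistics (reduced data carry
Gaussian-propagated one-standard-deviation errors). Every random draw is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .curves import ScatteringCurve
from .contrast import MolecularComposition, SolventSpec, excess_sld, parse_fraction
from .fitting import get_model, ModelSpec
from . import models as md

__all__ = [
    "NoiseSpec",
    "InstrumentSpec",
    "D11",
    "BT5",
    "INSTRUMENT_PRESETS",
    "DEFAULT_CONTRAST_FRACTIONS",
    "generate_curve",
    "generate_contrast_series",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise emulating counting statistics of reduced SANS data.

    ``mode="relative"``: sigma = max(relative_sigma * |I|, floor_sigma) —
    a flat fractional error, convenient for recovery studies.

    ``mode="counting"``: sigma = max(relative_sigma * sqrt(|I| * I_ref),
    min_relative_sigma * |I|, floor_sigma) with I_ref the median model
    intensity (or ``reference_intensity``). This reproduces the Poisson
    scaling of real measurements: strong low-q points are known to a small
    fraction of a percent while weak high-q points are noisy; the relative
    error equals ``relative_sigma`` at the median intensity. The
    ``min_relative_sigma`` floor models the calibration/systematics limit.
    """

    relative_sigma: float = 0.02
    floor_sigma: float = 0.0
    seed: int | None = None
    mode: str = "relative"
    reference_intensity: float | None = None
    min_relative_sigma: float = 0.002

    def __post_init__(self) -> None:
        if self.relative_sigma < 0 or self.floor_sigma < 0:
            raise ValueError("noise levels must be >= 0")
        if self.mode not in ("relative", "counting"):
            raise ValueError("mode must be 'relative' or 'counting'")

    def sigma_for(self, ideal: np.ndarray) -> np.ndarray:
        """Per-point standard deviation for a noiseless model curve."""
        ai = np.abs(ideal)
        if self.mode == "counting":
            ref = self.reference_intensity
            if ref is None:
                ref = float(np.median(ai))
            return np.maximum.reduce([
                self.relative_sigma * np.sqrt(ai * ref),
                self.min_relative_sigma * ai,
                np.full_like(ai, self.floor_sigma)])
        return np.maximum(self.relative_sigma * ai, self.floor_sigma)


@dataclass(frozen=True)
class InstrumentSpec:
    """q-grid and resolution of a pinhole SANS configuration."""

    q_min: float
    q_max: float
    n_points: int = 120
    spacing: str = "log"
    dq_over_q: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.q_min < self.q_max:
            raise ValueError("need 0 < q_min < q_max")
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10")
        if self.spacing not in ("log", "linear"):
            raise ValueError("spacing must be 'log' or 'linear'")
        if self.dq_over_q < 0:
            raise ValueError("dq_over_q must be >= 0")

    def q_grid(self) -> np.ndarray:
        if self.spacing == "log":
            return np.geomspace(self.q_min, self.q_max, self.n_points)
        return np.linspace(self.q_min, self.q_max, self.n_points)


# D11 pinhole camera: q 0.0013-0.4102 1/A, 9% FWHM wavelength spread
# (sigma ~ 0.09/2.355). BT5 is the USANS q-window (slit geometry is not
# emulated; the preset only provides the grid).
D11 = InstrumentSpec(q_min=0.0013, q_max=0.4102, n_points=120,
                     spacing="log", dq_over_q=0.038)
BT5 = InstrumentSpec(q_min=5e-5, q_max=1e-3, n_points=40,
                     spacing="log", dq_over_q=0.025)
INSTRUMENT_PRESETS = {"d11": D11, "bt5": BT5}

#: D2O volume fractions of the chitin contrast-variation series.
DEFAULT_CONTRAST_FRACTIONS = (0.0, 0.20, 0.42, 0.66, 0.80, 1.00)


ModelLike = "str | ModelSpec | Callable[[np.ndarray], np.ndarray]"


def _evaluate_model(model, params: Mapping[str, float] | None,
                    q: np.ndarray) -> np.ndarray:
    if callable(model) and not isinstance(model, ModelSpec):
        return np.asarray(model(q), dtype=float)
    spec = get_model(model)
    p = dict(spec.defaults)
    if params:
        p.update(params)
    return spec.evaluate(q, p)


def generate_curve(model, params: Mapping[str, float] | None,
                   instrument: InstrumentSpec,
                   noise: NoiseSpec | None = None,
                   metadata: Mapping | None = None) -> ScatteringCurve:
    """Simulate one reduced curve from a model on an instrument grid.

    The model is evaluated on the grid, optionally smeared with the
    instrument resolution, and perturbed with seeded Gaussian noise; the
    applied sigma is stored in the curve.
    """
    noise = noise or NoiseSpec()
    q = instrument.q_grid()
    ideal = _evaluate_model(model, params, q)
    if instrument.dq_over_q > 0:
        ideal = md.smear_gaussian(ideal, q, instrument.dq_over_q)
    sigma = noise.sigma_for(ideal)
    rng = np.random.default_rng(noise.seed)
    if np.any(sigma > 0):
        observed = ideal + rng.normal(size=q.size) * sigma
    else:
        observed = ideal.copy()
    sigma_stored = np.where(sigma > 0, sigma,
                            np.maximum(1e-6 * np.max(np.abs(ideal)), 1e-30))
    meta = {"synthetic": True, "noise_relative": noise.relative_sigma,
            "noise_seed": noise.seed, "dq_over_q": instrument.dq_over_q}
    if metadata:
        meta.update(metadata)
    return ScatteringCurve(
        q=q, intensity=observed, sigma_i=sigma_stored,
        sigma_q=instrument.dq_over_q * q if instrument.dq_over_q > 0 else None,
        metadata=meta)


_DEFAULT_SHAPE_PARAMS = {
    "alpha1": 1.0, "radius_R": 16.0, "contour_L_C": 5000.0,
    "kuhn_b": 318.0, "alpha2": 0.0, "decay_D": 4.0, "background_c": 0.0,
}


def generate_contrast_series(
        solute: MolecularComposition,
        fractions: Sequence[float] = DEFAULT_CONTRAST_FRACTIONS,
        forward_scale: float = 1.0,
        instrument: InstrumentSpec = D11,
        noise: NoiseSpec | None = None,
        shape_model="flexible_cylinder_powerlaw",
        shape_params: Mapping[str, float] | None = None,
        background: float = 0.0,
        exchange_fraction: float = 1.0,
) -> list[tuple[float, ScatteringCurve]]:
    """Simulate a D2O contrast-variation series of one particle species.

    A single fixed shape function P(q) (normalized to 1 at the grid's first
    point) is scaled by the squared excess scattering-length density at
    each D2O fraction, so the series' integrated intensity is an exact
    quadratic in the fraction with its minimum at the composition's match
    point. Noise realizations are independent across curves but derived
    from one master seed.
    """
    noise = noise or NoiseSpec()
    fracs = [parse_fraction(f) for f in fractions]
    q = instrument.q_grid()
    shape = _evaluate_model(shape_model,
                            shape_params or _DEFAULT_SHAPE_PARAMS, q)
    shape = shape / shape[0]
    children = np.random.SeedSequence(noise.seed).spawn(len(fracs))
    series: list[tuple[float, ScatteringCurve]] = []
    for f, child in zip(fracs, children):
        delta_rho = excess_sld(solute, SolventSpec(f, exchange_fraction))
        ideal = forward_scale * delta_rho**2 * shape + background
        child_seed = int(child.generate_state(1)[0] % (2**31))
        curve = generate_curve(
            lambda _q, vals=ideal: vals, None,
            replace(instrument, dq_over_q=0.0),
            replace(noise, seed=child_seed),
            metadata={"f_d2o": f, "contrast": delta_rho})
        series.append((f, curve))
    return series
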