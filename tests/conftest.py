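"""Shared fixtures: ground-truth parameter sets and stand-in curves.

Deposited-data stand-ins are synthetic: they are generated from the
published best-fit parameter values with counting-statistics noise, so
every fixture's truth is known by construction.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import gamma

from fibersans import fitting as ft
from fibersans import synth


# published best-fit values for the beta-chitin fiber curve
CHITIN_FIBER_TRUTH = {
    "alpha1": 1.0, "radius_R": 16.0, "contour_L_C": 5000.0,
    "kuhn_b": 318.0, "alpha2": 3e-10, "decay_D": 4.0,
    "background_c": 0.005,
}


def unified_level_b(G: float, D: float, Rg: float) -> float:
    """Mass-fractal link between the Guinier and power-law prefactors."""
    return G * D * gamma(D / 2.0) / Rg**D


def unified_truth(Rg1: float, D1: float, Rg2: float, D2: float,
                  G1: float = 1000.0, G2: float = 5.0,
                  background: float = 0.005) -> dict[str, float]:
    return {
        "G1": G1, "Rg1": Rg1, "D1": D1, "B1": unified_level_b(G1, D1, Rg1),
        "G2": G2, "Rg2": Rg2, "D2": D2, "B2": unified_level_b(G2, D2, Rg2),
        "background_c": background,
    }


def replicate_seeds(master: int, n: int) -> list[int]:
    """n independent 31-bit child seeds from one master seed."""
    return [int(c.generate_state(1)[0] % 2**31)
            for c in np.random.SeedSequence(master).spawn(n)]


def make_chitin_standin(seed: int,
                        noise_mode: str = "counting") -> "synth.ScatteringCurve":
    """Synthetic stand-in for the deposited chitin fiber curve."""
    return synth.generate_curve(
        "flexible_cylinder_powerlaw", CHITIN_FIBER_TRUTH, synth.D11,
        synth.NoiseSpec(relative_sigma=0.02, seed=seed, mode=noise_mode),
        metadata={"sample": "synthetic chitin fiber stand-in"})


@pytest.fixture(scope="session")
def d11_grid() -> np.ndarray:
    return synth.D11.q_grid()


@pytest.fixture(scope="session")
def chitin_standin():
    return make_chitin_standin(seed=7)
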