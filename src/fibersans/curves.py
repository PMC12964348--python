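"""Reduced small-angle scattering data container.

A :class:`ScatteringCurve` holds one reduced SAS dataset: the momentum
transfer grid ``q`` (1/Angstrom), absolute-scale intensities ``I(q)``
(1/cm), their one-standard-deviation uncertainties, and optionally a
per-point resolution width ``sigma_q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ScatteringCurve"]


@dataclass
class ScatteringCurve:
    """One reduced SAS curve.

    Parameters
    ----------
    q : array
        Momentum transfer, 1/Angstrom. Strictly increasing, all > 0.
    intensity : array
        Scattered intensity, 1/cm. May be negative after background
        subtraction.
    sigma_i : array
        One-standard-deviation uncertainty on ``intensity``, 1/cm; > 0.
    sigma_q : array, optional
        Gaussian resolution width per point, 1/Angstrom.
    metadata : dict
        Free-form provenance (sample label, ``f_d2o``, flags).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma_i: np.ndarray
    sigma_q: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma_i = np.asarray(self.sigma_i, dtype=float)
        if self.sigma_q is not None:
            self.sigma_q = np.asarray(self.sigma_q, dtype=float)
        n = self.q.size
        if n == 0:
            raise ValueError("empty curve")
        for name in ("intensity", "sigma_i"):
            if getattr(self, name).shape != self.q.shape:
                raise ValueError(f"{name} length does not match q")
        if self.sigma_q is not None and self.sigma_q.shape != self.q.shape:
            raise ValueError("sigma_q length does not match q")
        if not np.all(np.isfinite(self.q)) or np.any(self.q <= 0):
            raise ValueError("q must be finite and > 0")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(~np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if np.any(self.sigma_i <= 0) or np.any(~np.isfinite(self.sigma_i)):
            raise ValueError("sigma_i must be finite and > 0")

    def __len__(self) -> int:
        return int(self.q.size)

    def subrange(self, q_min: float | None = None,
                 q_max: float | None = None) -> "ScatteringCurve":
        """Return the curve restricted to ``q_min <= q <= q_max``."""
        lo = -np.inf if q_min is None else q_min
        hi = np.inf if q_max is None else q_max
        mask = (self.q >= lo) & (self.q <= hi)
        if not mask.any():
            raise ValueError(f"no points in q-window [{lo}, {hi}]")
        return ScatteringCurve(
            q=self.q[mask],
            intensity=self.intensity[mask],
            sigma_i=self.sigma_i[mask],
            sigma_q=None if self.sigma_q is None else self.sigma_q[mask],
            metadata=dict(self.metadata),
        )
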