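"""Weighted nonlinear least-squares fitting of scattering models.

The engine minimizes ``sum(((I_obs - I_model)/sigma)**2)`` with a
trust-region-reflective solver. Parameters that must stay positive (scales,
radii, lengths) enter the optimizer log-transformed, which conditions the
problem across the many decades a SANS curve spans; uncertainties are
propagated back to linear scale by the delta method. Goodness of fit is
reported as reduced chi-square, chi2_min / (n_points - n_free).

Model registry
--------------
Models are addressable by string key:

``power_law``
    alpha2 * q**(-decay_D) + background_c
``flexible_cylinder_powerlaw``
    the fiber model: wormlike chain with circular cross-section plus a
    low-q power law and flat background
``beaucage1`` / ``beaucage2`` / ``beaucage<N>``
    N-level unified model, level 1 the largest structure
``ellipsoid_chain``
    random-walk chain of identical ellipsoids (simulation/plotting aid)

Protocol helpers mirror the analysis the models were built for:
:func:`fit_chitin_reference` (contour length fixed at 5000 A) and
:func:`fit_beaucage_two_stage` (levels fitted individually on q-subranges
first, then combined, with Rg capped at pi/q_min).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .curves import ScatteringCurve
from . import models as md

__all__ = [
    "FitConfig",
    "FitResult",
    "ModelSpec",
    "get_model",
    "MODEL_KEYS",
    "fit_curve",
    "fit_beaucage_two_stage",
    "fit_chitin_reference",
]

_TINY = 1e-30


# ---------------------------------------------------------------------------
# model registry

@dataclass(frozen=True)
class ModelSpec:
    """A fittable model: flat scalar parameters and an evaluator."""

    name: str
    param_names: tuple[str, ...]
    defaults: dict[str, float]
    positive: frozenset[str]          # log-transformed during fitting
    evaluate: Callable[[np.ndarray, Mapping[str, float]], np.ndarray]
    default_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)


def _eval_power_law(q, p):
    return md.eval_power_law(q, p["alpha2"], p["decay_D"], p["background_c"])


def _eval_flex(q, p):
    params = md.FlexCylinderPowerlawParams(
        alpha1=p["alpha1"], radius_R=p["radius_R"],
        contour_L_C=p["contour_L_C"], kuhn_b=p["kuhn_b"],
        alpha2=p["alpha2"], decay_D=p["decay_D"],
        background_c=p["background_c"])
    return md.eval_flexible_cylinder(q, params)


def _beaucage_param_names(n_levels: int) -> tuple[str, ...]:
    names: list[str] = []
    for i in range(1, n_levels + 1):
        names += [f"G{i}", f"Rg{i}", f"B{i}", f"D{i}"]
    names.append("background_c")
    return tuple(names)


def _eval_beaucage_flat(n_levels: int):
    def evaluate(q, p):
        # ordered largest-first is a fitting-time convention; during
        # optimization levels may momentarily swap, so sort here
        levels = sorted(
            (md.BeaucageLevel(G=max(p[f"G{i}"], 0.0), Rg=p[f"Rg{i}"],
                              B=max(p[f"B{i}"], 0.0), D=p[f"D{i}"])
             for i in range(1, n_levels + 1)),
            key=lambda lv: -lv.Rg)
        # dataclass forbids equal Rg; nudge exact ties
        uniq = []
        for lv in levels:
            if uniq and lv.Rg >= uniq[-1].Rg:
                lv = md.BeaucageLevel(G=lv.G, Rg=uniq[-1].Rg * 0.999999,
                                      B=lv.B, D=lv.D)
            uniq.append(lv)
        params = md.BeaucageParams(levels=tuple(uniq),
                                   background_c=p["background_c"])
        return md.eval_beaucage(q, params)
    return evaluate


def _eval_ellipsoid_chain(q, p):
    params = md.EllipsoidChainParams.uniform(
        n_subunits=int(round(p["n_subunits"])),
        semi_axes=(p["axis_a"], p["axis_b"], p["axis_c"]),
        step_length=p["step_length"], scale=p["scale"],
        background=p["background"])
    return md.eval_ellipsoid_chain(q, params)


def _build_registry() -> dict[str, ModelSpec]:
    reg: dict[str, ModelSpec] = {}
    reg["power_law"] = ModelSpec(
        name="power_law",
        param_names=("alpha2", "decay_D", "background_c"),
        defaults={"alpha2": 1e-9, "decay_D": 4.0, "background_c": 0.0},
        positive=frozenset({"alpha2"}),
        evaluate=_eval_power_law,
        default_bounds={"decay_D": (0.0, 5.0), "background_c": (0.0, np.inf)},
    )
    reg["flexible_cylinder_powerlaw"] = ModelSpec(
        name="flexible_cylinder_powerlaw",
        param_names=("alpha1", "radius_R", "contour_L_C", "kuhn_b",
                     "alpha2", "decay_D", "background_c"),
        defaults={"alpha1": 1.0, "radius_R": 20.0, "contour_L_C": 5000.0,
                  "kuhn_b": 250.0, "alpha2": 1e-10, "decay_D": 4.0,
                  "background_c": 1e-3},
        positive=frozenset({"alpha1", "radius_R", "contour_L_C", "kuhn_b",
                            "alpha2"}),
        evaluate=_eval_flex,
        default_bounds={"decay_D": (1.0, 5.0), "background_c": (0.0, np.inf),
                        "radius_R": (1.0, 500.0), "kuhn_b": (5.0, 1e4)},
    )
    reg["ellipsoid_chain"] = ModelSpec(
        name="ellipsoid_chain",
        param_names=("n_subunits", "axis_a", "axis_b", "axis_c",
                     "step_length", "scale", "background"),
        defaults={"n_subunits": 5, "axis_a": 20.0, "axis_b": 15.0,
                  "axis_c": 15.0, "step_length": 35.0, "scale": 1.0,
                  "background": 0.0},
        positive=frozenset({"axis_a", "axis_b", "axis_c", "step_length",
                            "scale"}),
        evaluate=_eval_ellipsoid_chain,
        default_bounds={"background": (0.0, np.inf)},
    )
    return reg


_REGISTRY = _build_registry()
_BEAUCAGE_KEY = re.compile(r"^beaucage(\d+)$")


def get_model(key: "str | ModelSpec") -> ModelSpec:
    """Resolve a model key (``"beaucage2"`` etc.) to a :class:`ModelSpec`."""
    if isinstance(key, ModelSpec):
        return key
    if key in _REGISTRY:
        return _REGISTRY[key]
    m = _BEAUCAGE_KEY.match(key)
    if m:
        n = int(m.group(1))
        if not 1 <= n <= 9:
            raise KeyError(f"unsupported number of unified levels: {n}")
        names = _beaucage_param_names(n)
        defaults: dict[str, float] = {"background_c": 0.0}
        bounds: dict[str, tuple[float, float]] = {
            "background_c": (0.0, np.inf)}
        for i in range(1, n + 1):
            defaults.update({f"G{i}": 1.0, f"Rg{i}": 100.0 ** (1.0 / i) * 10,
                             f"B{i}": 1e-4, f"D{i}": 2.5})
            bounds[f"D{i}"] = (0.2, 4.5)
            bounds[f"Rg{i}"] = (1.0, np.inf)
        spec = ModelSpec(
            name=key, param_names=names, defaults=defaults,
            positive=frozenset({f"{p}{i}" for i in range(1, n + 1)
                                for p in ("G", "Rg", "B")}),
            evaluate=_eval_beaucage_flat(n), default_bounds=bounds)
        _REGISTRY[key] = spec
        return spec
    raise KeyError(f"unknown model {key!r}; known: {sorted(_REGISTRY)}")


MODEL_KEYS = ("power_law", "flexible_cylinder_powerlaw", "beaucage1",
              "beaucage2", "ellipsoid_chain")


# ---------------------------------------------------------------------------
# configuration and result containers

@dataclass
class FitConfig:
    """Options controlling a fit.

    ``weighting`` is ``"sigma"`` (1/sigma^2, default) or ``"none"``.
    ``fixed`` maps parameter names to frozen values. ``bounds`` entries
    override the model defaults. ``n_starts`` > 1 turns on seeded
    multi-start around the starting point.
    """

    start: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    weighting: str = "sigma"
    q_window: tuple[float, float] | None = None
    max_nfev: int | None = None
    tol: float = 1e-12
    seed: int | None = None
    n_starts: int = 1
    use_resolution: bool = True   # smear the model when data carry sigma_q

    def __post_init__(self) -> None:
        if self.weighting not in ("sigma", "none"):
            raise ValueError("weighting must be 'sigma' or 'none'")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bounds for {name!r} inverted")


@dataclass
class FitResult:
    """Estimates, uncertainties and provenance of one fit."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float]          # 1-sigma; NaN when undefined
    redchi: float
    chi2: float
    cov: np.ndarray | None            # linear scale, free params only
    free_names: tuple[str, ...]
    n_points: int
    n_free: int
    success: bool
    status_message: str
    constraints: list[str] = field(default_factory=list)
    at_bounds: tuple[str, ...] = ()
    warnings: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """Flat machine-readable report."""
        out: dict = {
            "model": self.model,
            "reduced_chi2": self.redchi,
            "n_points": self.n_points,
            "n_free": self.n_free,
            "success": self.success,
            "status": self.status_message,
            "constraints": list(self.constraints),
            "at_bounds": list(self.at_bounds),
            "warnings": list(self.warnings),
        }
        for k, v in self.params.items():
            out[k] = v
            out[f"{k}_stderr"] = self.stderr.get(k, 0.0)
        return out

    def format_report(self) -> str:
        """Table-style text report: estimate +/- 1 sigma per parameter."""
        lines = [f"model: {self.model}",
                 f"reduced chi2: {self.redchi:.4g} "
                 f"({self.n_points} points, {self.n_free} free)"]
        for k, v in self.params.items():
            err = self.stderr.get(k)
            if err is None or not np.isfinite(err):
                lines.append(f"  {k:>14s} = {v:12.6g}  (fixed or undefined)")
            else:
                lines.append(f"  {k:>14s} = {v:12.6g} +/- {err:.3g}")
        for c in self.constraints:
            lines.append(f"  constraint: {c}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# transform layer

class _Transform:
    """Map external parameters to optimizer space (log for positive ones)."""

    def __init__(self, names: Sequence[str], positive: frozenset[str],
                 bounds: Mapping[str, tuple[float, float]]):
        self.names = tuple(names)
        self.is_log = tuple(n in positive for n in self.names)
        lo, hi = [], []
        for n, lg in zip(self.names, self.is_log):
            b = bounds.get(n, (-np.inf, np.inf))
            if lg:
                lo.append(np.log(max(b[0], _TINY)))
                hi.append(np.log(b[1]) if np.isfinite(b[1]) else np.inf)
            else:
                lo.append(b[0])
                hi.append(b[1])
        self.lower = np.array(lo)
        self.upper = np.array(hi)

    def to_internal(self, values: Mapping[str, float]) -> np.ndarray:
        z = np.array([np.log(max(values[n], _TINY)) if lg else values[n]
                      for n, lg in zip(self.names, self.is_log)])
        return np.clip(z, self.lower, self.upper)

    def to_external(self, z: np.ndarray) -> dict[str, float]:
        # cap at exp(600) so wild multi-start excursions stay finite
        return {n: float(np.exp(min(v, 600.0))) if lg else float(v)
                for n, v, lg in zip(self.names, z, self.is_log)}

    def jacobian_scale(self, z: np.ndarray) -> np.ndarray:
        """diag(d external / d internal) at z."""
        return np.array([np.exp(v) if lg else 1.0
                         for v, lg in zip(z, self.is_log)])


# ---------------------------------------------------------------------------
# core fit

def fit_curve(data: ScatteringCurve, model: "str | ModelSpec",
              config: FitConfig | None = None) -> FitResult:
    """Weighted least-squares fit of ``model`` to ``data``.

    Non-convergence is flagged on the result (``success=False``), not
    raised; a singular covariance yields NaN uncertainties.
    """
    spec = get_model(model)
    cfg = config or FitConfig()
    if cfg.q_window is not None:
        data = data.subrange(*cfg.q_window)
    q, iobs = data.q, data.intensity
    sigma = data.sigma_i if cfg.weighting == "sigma" else np.ones_like(iobs)
    dq_over_q = None
    if cfg.use_resolution and data.sigma_q is not None:
        ratio = float(np.median(data.sigma_q / q))
        if ratio > 0:
            dq_over_q = ratio

    values = dict(spec.defaults)
    values.update(cfg.start)
    values.update(cfg.fixed)
    unknown = set(values) - set(spec.param_names)
    if unknown:
        raise ValueError(f"unknown parameters for {spec.name}: {sorted(unknown)}")

    free = [n for n in spec.param_names if n not in cfg.fixed]
    n_free = len(free)
    if len(data) <= n_free:
        raise ValueError(
            f"{len(data)} points cannot constrain {n_free} free parameters")

    bounds = dict(spec.default_bounds)
    bounds.update(cfg.bounds)
    for name, (lo, hi) in bounds.items():
        if name in values:
            values[name] = float(np.clip(values[name], lo, hi))
    tr = _Transform(free, spec.positive, bounds)

    fixed_vals = {n: values[n] for n in spec.param_names if n in cfg.fixed}

    def residual(z: np.ndarray) -> np.ndarray:
        p = tr.to_external(z)
        p.update(fixed_vals)
        model_i = spec.evaluate(q, p)
        if dq_over_q is not None:
            model_i = md.smear_gaussian(model_i, q, dq_over_q)
        r = (model_i - iobs) / sigma
        # keep wild multi-start excursions finite for the optimizer
        return np.clip(np.nan_to_num(r, nan=1e50, posinf=1e50,
                                     neginf=-1e50), -1e50, 1e50)

    z0 = tr.to_internal({n: values[n] for n in free})
    starts = [z0]
    if cfg.n_starts > 1:
        rng = np.random.default_rng(cfg.seed)
        span = np.where(np.isfinite(tr.upper - tr.lower),
                        tr.upper - tr.lower, 2.0)
        for _ in range(cfg.n_starts - 1):
            jitter = rng.normal(0.0, 0.25, size=z0.size) * np.minimum(span, 2.0)
            starts.append(np.clip(z0 + jitter, tr.lower, tr.upper))

    best = None
    for zs in starts:
        try:
            sol = least_squares(
                residual, zs, bounds=(tr.lower, tr.upper), method="trf",
                x_scale="jac", ftol=cfg.tol, xtol=cfg.tol, gtol=cfg.tol,
                max_nfev=cfg.max_nfev)
        except (ValueError, FloatingPointError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    p_hat = tr.to_external(best.x)
    all_params = dict(fixed_vals)
    all_params.update(p_hat)
    all_params = {n: all_params[n] for n in spec.param_names}

    chi2 = 2.0 * best.cost
    dof = len(data) - n_free
    redchi = chi2 / dof

    stderr = {n: np.nan for n in spec.param_names}
    for n in fixed_vals:
        stderr[n] = 0.0
    cov_ext: np.ndarray | None = None
    warnings_list: list[str] = []
    if n_free > 0:
        jac = best.jac
        try:
            u, s, vt = np.linalg.svd(jac, full_matrices=False)
        except np.linalg.LinAlgError:
            s = np.array([0.0])
        if s.size and s[0] > 0 and s[-1] > np.finfo(float).eps * max(jac.shape) * s[0]:
            cov_z = (vt.T / s**2) @ vt * (chi2 / dof if dof > 0 else 1.0)
            scale = tr.jacobian_scale(best.x)
            cov_ext = cov_z * np.outer(scale, scale)
            for i, n in enumerate(free):
                stderr[n] = float(np.sqrt(max(cov_ext[i, i], 0.0)))
        else:
            warnings_list.append("singular covariance; uncertainties undefined")

    at_bounds = []
    for i, n in enumerate(free):
        lo, hi = tr.lower[i], tr.upper[i]
        width = (hi - lo) if np.isfinite(hi - lo) else 1.0
        tol = max(1e-8, 1e-6 * abs(width) if np.isfinite(width) else 1e-8)
        if (np.isfinite(lo) and best.x[i] - lo < tol) or \
           (np.isfinite(hi) and hi - best.x[i] < tol):
            at_bounds.append(n)

    constraints = [f"fixed {n} = {v:g}" for n, v in fixed_vals.items()]
    constraints += [f"bound {n} in [{bounds[n][0]:g}, {bounds[n][1]:g}]"
                    for n in free if n in bounds]

    success = bool(best.status > 0)
    if not success:
        warnings_list.append("optimizer did not converge")

    return FitResult(
        model=spec.name, params=all_params, stderr=stderr, redchi=redchi,
        chi2=chi2, cov=cov_ext, free_names=tuple(free), n_points=len(data),
        n_free=n_free, success=success, status_message=str(best.message),
        constraints=constraints, at_bounds=tuple(at_bounds),
        warnings=warnings_list)


# ---------------------------------------------------------------------------
# protocol fits

def _loglog_slope(q: np.ndarray, i: np.ndarray) -> float:
    pos = i > 0
    if pos.sum() < 3:
        return -3.0
    return float(np.polyfit(np.log(q[pos]), np.log(i[pos]), 1)[0])


def _single_level_starts(curve: ScatteringCurve,
                         rg_max: float) -> dict[str, float]:
    """Heuristic one-level unified starts from a (sub)curve."""
    q, i = curve.q, curve.intensity
    n = len(q)
    hi = slice(max(n // 2, n - max(n // 3, 3)), n)
    d0 = float(np.clip(-_loglog_slope(q[hi], i[hi]), 0.3, 4.4))
    b0 = float(max(np.median(i[hi] * q[hi] ** d0), 1e-12))
    # Guinier slope on the low end of the subrange
    lo = slice(0, max(3, n // 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.log(np.clip(i[lo], 1e-300, None))
    slope = np.polyfit(q[lo] ** 2, y, 1)[0]
    if slope < 0:
        rg0 = float(np.sqrt(min(-3.0 * slope, rg_max**2)))
    else:
        rg0 = 1.5 / float(np.sqrt(q[0] * q[-1]))
    rg0 = float(np.clip(rg0, 2.0, rg_max))
    g0 = float(max(i[0] - b0 * q[0] ** (-d0), i[0] * 0.1, 1e-9))
    return {"G1": g0, "Rg1": rg0, "B1": b0, "D1": d0}


def fit_beaucage_two_stage(data: ScatteringCurve, n_levels: int = 2,
                           config: FitConfig | None = None,
                           q_split: float | None = None) -> FitResult:
    """Two-stage unified fit: levels individually, then combined.

    Stage 1 fits a single-level model on the low-q subrange (largest
    structure) and on the high-q subrange; stage 2 fits the combined
    model starting from the stage-1 estimates, with multi-start. All Rg
    are bounded above by pi/q_min so no reported size exceeds the window
    the data can see.
    """
    if n_levels != 2:
        raise ValueError("the two-stage protocol is defined for 2 levels")
    cfg = config or FitConfig()
    if cfg.q_window is not None:
        data = data.subrange(*cfg.q_window)
    q_min, q_max = float(data.q[0]), float(data.q[-1])
    if q_max / q_min < 30:
        raise ValueError("q-range too narrow to separate two levels")
    rg_max = np.pi / q_min
    split = q_split if q_split is not None else float(np.sqrt(q_min * q_max))

    warnings_list: list[str] = []
    stage1: dict[str, dict[str, float]] = {}
    for tag, (lo, hi) in (("low", (q_min, split)), ("high", (split, q_max))):
        sub = data.subrange(lo, hi)
        sub_rg_max = rg_max if tag == "low" else np.pi / split
        starts = _single_level_starts(sub, sub_rg_max)
        try:
            res = fit_curve(
                sub, "beaucage1",
                FitConfig(start=starts,
                          fixed={} if tag == "high" else {"background_c": 0.0},
                          bounds={"Rg1": (2.0, sub_rg_max)},
                          weighting=cfg.weighting, seed=cfg.seed))
            if not res.success:
                raise RuntimeError(res.status_message)
            stage1[tag] = {k: res.params[k] for k in
                           ("G1", "Rg1", "B1", "D1", "background_c")}
        except (RuntimeError, ValueError) as exc:
            warnings_list.append(
                f"stage-1 fit on {tag}-q subrange failed ({exc}); "
                "using heuristic starts")
            starts["background_c"] = 0.0 if tag == "low" else float(
                max(np.min(sub.intensity), 0.0))
            stage1[tag] = starts

    combined_start = {
        "G1": stage1["low"]["G1"], "Rg1": stage1["low"]["Rg1"],
        "B1": stage1["low"]["B1"], "D1": stage1["low"]["D1"],
        "G2": stage1["high"]["G1"], "Rg2": stage1["high"]["Rg1"],
        "B2": stage1["high"]["B1"], "D2": stage1["high"]["D1"],
        "background_c": stage1["high"]["background_c"],
    }
    if combined_start["Rg2"] >= combined_start["Rg1"]:
        combined_start["Rg2"] = combined_start["Rg1"] / 10.0

    bounds = {"Rg1": (2.0, rg_max), "Rg2": (2.0, rg_max)}
    bounds.update(cfg.bounds)
    stage2_cfg = FitConfig(
        start=combined_start, bounds=bounds, fixed=dict(cfg.fixed),
        weighting=cfg.weighting, seed=cfg.seed,
        n_starts=max(cfg.n_starts, 5), max_nfev=cfg.max_nfev, tol=cfg.tol)
    result = fit_curve(data, "beaucage2", stage2_cfg)

    # canonical ordering: level 1 carries the larger Rg
    p = result.params
    if p["Rg1"] < p["Rg2"]:
        swap = {}
        for a, b in (("1", "2"), ("2", "1")):
            for stem in ("G", "Rg", "B", "D"):
                swap[f"{stem}{a}"] = p[f"{stem}{b}"]
        result.params.update(swap)
        err = result.stderr
        swap_e = {f"{s}{a}": err[f"{s}{b}"]
                  for a, b in (("1", "2"), ("2", "1"))
                  for s in ("G", "Rg", "B", "D")}
        result.stderr.update(swap_e)
        result.warnings.append("levels swapped to canonical (Rg1 > Rg2) order")

    # chi2 of the concatenated stage-1 parameters, for protocol auditing
    concat_eval = get_model("beaucage2").evaluate(data.q, combined_start)
    sigma = data.sigma_i if cfg.weighting == "sigma" else np.ones(len(data))
    chi2_concat = float(np.sum(((concat_eval - data.intensity) / sigma) ** 2))
    result.extra["stage1"] = stage1
    result.extra["stage1_concat_chi2"] = chi2_concat
    result.extra["q_split"] = split
    result.constraints.append(f"Rg <= pi/q_min = {rg_max:.4g}")
    result.warnings.extend(warnings_list)
    return result


def fit_chitin_reference(data: ScatteringCurve,
                         config: FitConfig | None = None) -> FitResult:
    """Fiber reference fit: flexible cylinder + power law, L_C fixed.

    The contour length is fixed at 5000 A (about 2 pi / q_min of the
    measured window): fiber lengths beyond the window cannot be inferred
    from the data and would only destabilize the fit.
    """
    cfg = config or FitConfig()
    work = data.subrange(*cfg.q_window) if cfg.q_window else data
    q, i = work.q, work.intensity

    c0 = float(max(np.min(i) * 0.8, 1e-6))
    n_low = max(5, len(q) // 8)
    d0 = float(np.clip(-_loglog_slope(q[:n_low], i[:n_low]), 1.5, 4.8))
    a2_0 = float(max(np.median((i[:n_low] - c0) * q[:n_low] ** d0) * 0.8,
                     1e-14))
    # fiber scale from the mid-q region where the power law has decayed:
    # alpha1 ~ residual intensity / (chain factor * cross-section factor)
    r0, b0 = 18.0, 250.0
    mid = min(np.searchsorted(q, np.sqrt(q[0] * q[-1])), len(q) - 1)
    resid_mid = max(i[mid] - a2_0 * q[mid] ** (-d0) - c0, i[mid] * 0.02)
    shape_mid = float(
        md.wormlike_chain_factor(np.array([q[mid]]), 5000.0, b0)[0]
        * md.cross_section_factor(np.array([q[mid]]), r0)[0])
    start = {"alpha1": float(resid_mid / max(shape_mid, 1e-6)),
             "radius_R": r0, "kuhn_b": b0, "alpha2": a2_0,
             "decay_D": min(d0, 4.8), "background_c": c0}
    start.update(cfg.start)
    fixed = {"contour_L_C": 5000.0}
    fixed.update(cfg.fixed)
    bounds = {"decay_D": (1.0, 5.0), "radius_R": (2.0, 200.0),
              "kuhn_b": (10.0, 5000.0)}
    bounds.update(cfg.bounds)
    fit_cfg = FitConfig(start=start, bounds=bounds, fixed=fixed,
                        weighting=cfg.weighting, q_window=cfg.q_window,
                        seed=cfg.seed, n_starts=max(cfg.n_starts, 5),
                        max_nfev=cfg.max_nfev, tol=cfg.tol)
    return fit_curve(data, "flexible_cylinder_powerlaw", fit_cfg)
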