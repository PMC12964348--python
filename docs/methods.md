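# Methods

This note records the models, numerical choices and deliberate design
decisions behind `fibersans`, and what the synthetic-data validation does
and does not demonstrate about real measurements.

## Scattering-length densities and match points

SLDs are computed from a small embedded table of bound coherent neutron
scattering lengths (Sears 1992; H −3.739, D 6.671, C 6.646, N 9.36,
O 5.803, S 2.804 fm, plus a few common hetero-elements) and molecular
volumes from mass density, `V = M/(ρ N_A)`. No partial-specific-volume
tables are used: for crystalline fibers like β-chitin the mass density is
the quantity practitioners actually know (1.5 g/mL is the standard fiber
value), and it makes the volume model explicit.

Hydrogen bookkeeping: non-labile H may be biosynthetically deuterated
(`deuteration_fraction`); labile H (N–H/O–H) carries the solvent-weighted
length `b_H + x·f·(b_D − b_H)` with `f` the D₂O volume fraction and `x`
the exchange fraction (default 1.0 — full equilibration; configurable
because real fibers may shield some sites, one reason theoretical and
measured match points can differ by a few percent). The molar mass used
for the volume keeps labile H as ¹H, i.e. the as-weighed protiated mass;
the exchange-induced mass change (<1 %) is deliberately ignored.

Solvent SLD is linear in `f` between pure-water endpoints computed at
25 °C densities (0.9970 and 1.1044 g/mL), i.e. ideal volume mixing. With
these inputs the GlcNAc anhydro unit (C₈H₁₃NO₅, 3 labile H) at 1.5 g/mL
matches at 44.6 % D₂O.

The series estimator mirrors experimental practice: trapezoid integration
of each curve on its native grid over 0.03–0.4 Å⁻¹ (no interpolation or
resampling, so the estimator is applicable to arbitrary deposited grids),
then the abscissa of the minimum of a fitted second-degree polynomial in
`f`. Because coherent intensity scales with contrast², the integrated
intensity is exactly quadratic for a single-component series; a
downward-opening or flat quadratic raises an error instead of returning a
spurious minimum.

## Wormlike-chain (flexible-cylinder) form factor

The chain factor `P(q)` is normalized to 1 at q = 0 and multiplied by a
circular cross-section factor `[2J₁(qR)/(qR)]²`.

For contour-to-Kuhn ratios n = L/b > 5 it follows the
Pedersen–Schurtenberger "method 3" interpolation with excluded volume:

- ideal-chain radius of gyration from the Benoit–Doty expression, scaled
  by the excluded-volume expansion factor
  `α²(n) = [1 + (n/3.12)² + (n/8.67)³]^(0.176/3)`;
- low q: a Debye function blended through a tanh switch (center 1.523,
  width 0.1477 in x = qR_g) into the asymptotic excluded-volume power law
  `1.22 x^(−1/ν) + 0.4288 x^(−2/ν) − 1.651 x^(−3/ν)`, ν = 0.585, plus a
  stiffness correction `C(n)·(b/L)·[4/15 + 7/(15u) − (11/15 + 7/(15u))e^(−u)]`
  with `C = 3.06 n^(−0.44)` for n > 10;
- high q (qb > 3.1): rod scattering `π/(qL)` plus two empirical power
  terms `a₁(qb)^(−4.12) + a₂(qb)^(−4.42)` whose coefficients are fixed by
  requiring the intensity and its first q-derivative to be continuous at
  the crossover. The two coefficients are obtained numerically (2×2 linear
  solve with a finite-difference derivative) rather than from transcribed
  closed-form expressions; the construction is identical and the numerical
  route is easier to audit.

Numerical guards: the power-law part of the blend is dropped below
x = qR_g = 1, where its weight is < 10⁻³ but the x^(−3/ν) term grows
without bound (the discontinuity introduced is ~10⁻⁶); Debye and
stiffness-correction functions switch to series forms at small argument;
the Benoit–Doty formula switches to its small-n series below n = 0.05
where the closed form cancels catastrophically.

For n ≤ 3 the package uses the Kholodenko wormlike-chain interpolation
(Gauss–Legendre quadrature of the hyperbolic/trigonometric kernel, 96
points), which is exact in both the rigid-rod and Debye-coil limits;
excluded volume is negligible for such short, stiff chains, and the
first-order (b/L) stiffness correction used above is a long-chain
expansion that fails badly near n ≈ 1. The two parameterizations are
blended with a cosine ramp over n ∈ [3, 5] so the model stays continuous
in (L, b) for gradient-based fitting. All fits in the package's intended
regime (chitin: n ≈ 15.7) use the long-chain branch.

## Unified (Beaucage) model

Per level i (ordered largest structure first), a Guinier term plus a
power-law term in the error-function crossover variable
`qᵢ* = q·erf(qR_gᵢ/√6)⁻³`, damped at low q by the next level's Guinier
factor `exp(−q²R_g(i+1)²/3)`; the last level takes R_g(N+1) = 0, the
standard convention when no sub-level exists. The power term is
evaluated as `[erf(qR_g/√6)]^(3D) · q^(−D)`, which goes to zero smoothly
as q → 0 (erf³ ~ q³) and never overflows for q > 0.

## Ellipsoid chain

N triaxial ellipsoids with centers on a random walk of step d, in the
decoupling approximation:

    I(q) ∝ Σᵢ wᵢ²⟨Fᵢ²⟩ + Σᵢ≠ⱼ wᵢwⱼ⟨Fᵢ⟩⟨Fⱼ⟩ [sin(qd)/(qd)]^|i−j|

with volume weights wᵢ and orientation averages by 32×32 Gauss–Legendre
quadrature over one octant (exploiting ellipsoid symmetry). Normalization
gives I(0) = scale + background exactly. The random-walk interference
factor `sinc^|i−j|` is the isotropic average over uncorrelated step
directions. This model describes an extended multi-domain protein (a
single ellipsoid underfits elongated four-domain architectures; about
five subunits reproduce such curves); it is provided as an evaluator and
simulation model, not as a protocol fit, since its use on real data is
qualitative.

## Resolution smearing

Pinhole resolution is modeled as a Gaussian in q with constant relative
width σ_q/q. Smearing of a curve known on a fixed grid uses 21-point
Gauss–Hermite quadrature, log-log interpolation between grid points and
local power-law extrapolation beyond the ends (after shifting by the
curve minimum so logs stay defined, which makes a constant curve exactly
invariant). The D11-like preset uses σ_q/q = 0.038, a 9 % FWHM wavelength
spread divided by 2√(2 ln 2); wavelength spread dominates over collimation
for such cameras at mid/high q, and a single relative width keeps the
operator diagonal-free and fast. Slit-smeared (USANS) geometry is out of
scope; the BT5 preset supplies only the q-window.

## Fitting

`fit_curve` minimizes `Σ[(I − I_model)/σ]²` with scipy's trust-region
reflective least squares. Parameters that must stay positive (scales,
radii, lengths, R_g) enter as logarithms — SANS parameters span many
decades and the log transform both enforces positivity and conditions the
Jacobian; uncertainties are mapped back by the delta method
(σ_p = p·σ_log p), and the covariance is reported in linear space.
Defaults: 1/σ² weighting; reduced χ² = χ²_min/(n − p); 1σ errors from the
SVD-based covariance at the optimum (NaN when the Jacobian is rank
deficient); non-convergence is flagged on the result rather than raised.
When the data carry a σ_q column the model is smeared with the median
σ_q/q inside the residual, so curves simulated (or measured) at finite
resolution are fitted without bias.

Multi-start (default 5 seeded starts, jitter 0.25 in log-space) guards
against the multimodality of unified fits. Residuals are clipped to
±10⁵⁰ so a wild start cannot overflow the optimizer.

Protocol fits:

- `fit_chitin_reference`: flexible cylinder + power law with the contour
  length fixed at 5000 Å ≈ 2π/q_min — fiber lengths beyond the measured
  window are not inferable and would destabilize the fit. Starting values
  come from the data (power-law slope and amplitude of the lowest decade,
  background from the minimum intensity, fiber scale from the mid-q
  residual divided by the chain factor).
- `fit_beaucage_two_stage`: stage 1 fits one level on the low-q subrange
  and one on the high-q subrange (split at the geometric mean of the
  q-range unless overridden — the protocol does not prescribe a split, and
  the geometric mean is the symmetric choice on a log grid); stage 2 fits
  the combined two-level model starting from the stage-1 estimates with
  multi-start, which by construction can only improve on the concatenated
  stage-1 parameters. Every R_g is bounded above by π/q_min so no reported
  size exceeds what the window can see; a fit pinned at that bound is
  flagged. Levels are reported in canonical order (R_g1 > R_g2); the
  evaluator sorts levels, so the ordering is a labeling convention, not a
  constraint on the optimizer. Stage-1 failures fall back to heuristic
  starts (log-log slope for D, Guinier slope for R_g) with a warning in
  the result log.

## Synthetic data: what it emulates, and what it does not

`generate_curve` evaluates a model on a log-spaced instrument grid
(D11-like preset: 120 points over 0.0013–0.4102 Å⁻¹), applies Gaussian
resolution smearing, and adds seeded Gaussian noise; the applied σ is
stored with the curve, as in reduced data. Two noise modes:

- `relative`: σ = max(rel·I, floor) — flat fractional error, the
  convention used for the parameter-recovery studies (2–3 %);
- `counting`: σ = max(rel·√(I·I_ref), 0.002·I, floor) with I_ref the
  median intensity — Poisson scaling, so strong low-q points are known to
  a fraction of a percent while weak high-q points are noisy, with a 0.2 %
  relative floor for the calibration/systematics limit. This mode is used
  for stand-ins for deposited measurements; under it the fiber fit returns
  σ_R ≈ 0.3 Å and σ_b ≈ 5–8 Å, consistent with the precision real
  measurements of this kind report.

`generate_contrast_series` scales one fixed shape function by contrast²
per D₂O fraction (defaults 0/20/42/66/80/100 %) with independent child
seeds from one master seed. A single shape across fractions encodes the
match-point procedure's own assumption (no H/D-induced shape change).

Not emulated: incoherent-background differences between H₂O and D₂O
buffers beyond a flat term, inter-particle structure factors,
sedimentation/aggregation kinetics, slit smearing, and cosmic/detector
artifacts. Passing recovery tests therefore demonstrate that the
estimators are consistent and correctly implemented under the stated
statistical model — not that real fibrous samples (where aggregation and
irreproducible network structure dominate systematic error) will yield
parameters at this precision.

Stand-in generation for validation against published fiber/complex fits
uses scales chosen to mimic realistic absolute intensities: fiber curve
α₁ = 1 cm⁻¹, α₂ = 3·10⁻¹⁰, c = 0.005 cm⁻¹; two-level aggregate curves
with G₁ = 1000, G₂ = 5 cm⁻¹ and the mass-fractal link
B = G·D·Γ(D/2)/R_g^D between each level's prefactors (forward scattering
of order 10²–10³ cm⁻¹, as observed for protein-bridged fiber networks).

## Known limitations

- The match point from composition is only as good as the density,
  exchange and purity assumptions; for chitin the spread between
  theoretical (~44 %) and measured (~47 %) values is attributed to exactly
  these, so `exchange_fraction` and density are explicit knobs rather
  than constants.
- The excluded-volume wormlike-chain parameterization is empirical; other
  implementations include a small monotonicity patch in the tanh-blend
  window which is omitted here (effect ≲1 % over a narrow q-band).
- `q_i*` crossovers make multi-level unified fits weakly identifiable
  when levels overlap; the two-stage protocol plus multi-start mitigates
  but does not eliminate local minima.
- Reported uncertainties are covariance-based (local, Gaussian); no
  posterior sampling.
- Problem sizes in the test suite (120-point grids, 4 replicate curves
  per stand-in comparison, 50 replicates for χ² calibration) are the
  package's chosen validation scale; estimator variances at other sizes
  follow the usual √n scaling.
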