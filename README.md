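# fibersans

Small-angle neutron scattering (SANS) analysis for protein–polysaccharide
fiber systems: neutron contrast matching, the form-factor models relevant
to rigid biopolymer nanofibers and their protein coats, and constrained
weighted least-squares fitting — plus a synthetic-data generator so the
whole chain can be validated against known ground truth.

The motivating system is the *Vibrio cholerae* colonization factor GbpA
bound to β-chitin nanofibers. Chitin (a GlcNAc homopolymer) is insoluble,
so solution structural work on the complex requires measuring at the
chitin contrast match point — the D₂O/H₂O ratio at which the fiber's
scattering-length density (SLD) equals the solvent's and the fiber becomes
invisible to neutrons — while the protein is perdeuterated to keep
contrast. The package covers each stage of that workflow for anyone doing
contrast-variation SANS on fibrous biopolymer complexes.

## What it computes

**Contrast and match points** (`fibersans.contrast`). SLDs from embedded
bound-coherent scattering lengths; labile (N–H/O–H) hydrogens carry the
solvent-weighted scattering length, so the component SLD is affine in the
D₂O volume fraction `f`:

    ρ_comp(f) = Σb(f) / V,   V = M / (ρ_mass · N_A),
    match point: ρ_comp(f*) = ρ_solv(f*)   (closed form)

and the experimental estimator: trapezoid-integrate each curve of a
contrast series over a q-window (default 0.03–0.4 Å⁻¹), fit a
second-degree polynomial of integrated intensity vs `f`, take its minimum.

**Form factors** (`fibersans.models`), all on arbitrary q-grids:

- flexible cylinder + power law,
  `I(q) = α₁ P_flex(q; R, L_C, b_Kuhn) + α₂ q^(−D) + c`, with the
  wormlike-chain factor in the excluded-volume ("method 3")
  parameterization and a circular cross-section `[2J₁(qR)/(qR)]²`;
- the N-level unified (Beaucage) model,
  `I(q) = c + Σᵢ Gᵢ exp(−q²Rgᵢ²/3) + Bᵢ exp(−q²Rg_{i+1}²/3) (1/qᵢ*)^{Dᵢ}`
  with `qᵢ* = q [erf(qRgᵢ/√6)]⁻³`;
- a random-walk chain of ellipsoids (decoupling approximation) for
  multi-domain proteins;
- Gaussian resolution smearing with σ_q = (Δq/q)·q.

**Fitting** (`fibersans.fitting`). Trust-region least squares of
`Σ[(I_obs − I_model)/σ]²` with log-transformed positive parameters,
1σ uncertainties from the covariance, reduced χ², multi-start, and the
protocol fits: `fit_chitin_reference` (contour length fixed at 5000 Å)
and `fit_beaucage_two_stage` (levels fitted individually on q-subranges,
then combined, with every Rg capped at π/q_min). Curves carrying a σ_q
column are fitted with the model smeared by the instrument resolution.

**Synthetic data** (`fibersans.synth`). D11-like curves
(q = 0.0013–0.4102 Å⁻¹, Δλ/λ = 9 %) from any model with seeded Gaussian
noise (flat-relative or counting-statistics mode), and contrast-variation
series at 0/20/42/66/80/100 % D₂O whose integrated intensity is exactly
quadratic in `f` with its minimum at the composition's match point.

## Worked example

```python
from fibersans import chitin_composition, match_point, fit_chitin_reference
from fibersans import synth

# 1) theoretical chitin match point (GlcNAc anhydro unit, 3 labile H,
#    fiber density 1.5 g/mL)
mp = match_point(chitin_composition(mass_density=1.5))
print(f"chitin match point: {100 * mp.fraction:.1f}% D2O")

# 2) simulate a chitin-fiber curve and fit it back
truth = {"alpha1": 1.0, "radius_R": 16.0, "contour_L_C": 5000.0,
         "kuhn_b": 318.0, "alpha2": 3e-10, "decay_D": 4.0,
         "background_c": 0.005}
curve = synth.generate_curve("flexible_cylinder_powerlaw", truth,
                             synth.D11,
                             synth.NoiseSpec(0.02, seed=7, mode="counting"))
res = fit_chitin_reference(curve)
print(f"R = {res.params['radius_R']:.1f} +/- {res.stderr['radius_R']:.1f} A, "
      f"b_Kuhn = {res.params['kuhn_b']:.0f} +/- {res.stderr['kuhn_b']:.0f} A, "
      f"reduced chi2 = {res.redchi:.2f}")
```

Output:

```
chitin match point: 44.6% D2O
R = 16.1 +/- 0.3 A, b_Kuhn = 323 +/- 6 A, reduced chi2 = 0.72
```

The match point says a 44–45 % D₂O buffer hides the fiber; the fit
recovers the generating radius (16 Å ≈ the chitin nanofiber cross-section)
and Kuhn length (≈318 Å, a very rigid polymer — the Kuhn length is twice
the persistence length) within their 1σ uncertainties.

The same operations are available from the shell:

```sh
fibersans matchpoint --formula C8H13NO5 --labile-h 3 --density 1.5
fibersans simulate --model flexible_cylinder_powerlaw --seed 7 --out sim.dat
fibersans fit --data sim.dat --model chitin_reference --outdir out/
```

Each command writes a JSON run report (config snapshot, input digests,
results, warnings) that makes the run reproducible.

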