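# Methods

## Constitutive model

Soft tissues (brain regions, cerebral vasculature, dura) are modelled as
incompressible, isotropic, hyperelastic–viscoelastic solids.  The elastic
backbone is an N-term Ogden strain-energy density in principal stretches,

W = Σᵢ (2 μᵢ / αᵢ²) (λ₁^αᵢ + λ₂^αᵢ + λ₃^αᵢ − 3),   λ₁λ₂λ₃ = 1,

in the convention where Σμᵢ is the small-strain shear modulus (so the μ
column of the parameter table is directly a shear modulus in kPa).  Other
Ogden conventions differ by factors of αᵢ/2 in μᵢ; the convention string is
recorded in every exported material card.  The energy form is singular at
α = 0, so |αᵢ| ≥ 0.1 is enforced.

Two homogeneous test modes are supported, each with the hydrostatic
pressure eliminated analytically by its traction-free boundary:

- **Simple shear** (plate-on-plate, γ = plate displacement / sample
  thickness): principal stretches (λ, 1/λ, 1), λ = γ/2 + √(1 + γ²/4);
  Cauchy shear stress σ₁₂ = Σᵢ (2μᵢ/αᵢ)(λ^αᵢ − λ^−αᵢ)/(λ + 1/λ) = dW/dγ.
- **Incompressible uniaxial tension** (λ, λ^-½, λ^-½): Cauchy stress
  σ₁₁ = Σᵢ (2μᵢ/αᵢ)(λ^αᵢ − λ^−αᵢ/2) = λ dW/dλ; nominal stress P₁₁ = σ₁₁/λ.

Because both test stresses are purely deviatoric under incompressibility,
the bulk modulus (2.19 GPa for these tissues) never enters the fit and is
carried as metadata only.  Shear curves are Cauchy shear stress; uniaxial
curves default to Cauchy (true) stress with a `stress_measure="nominal"`
switch, since force/area reductions in the source experiments could be
either.  Compression, anisotropy, damage/failure and vessel
inflation–extension coupling are out of scope; the artery test is
idealised as pure uniaxial tension (the 80/120 mmHg luminal-pressure
groups were pooled experimentally, so pressurisation is treated as
non-informative).

## Viscoelasticity

Rate dependence uses quasi-linear viscoelasticity: the measured stress of
each test is the scalar hereditary convolution

σ(t) = ∫₀ᵗ g_R(t−s) dσᵉ/ds ds,   g_R(t) = 1 − Σᵢ gᵢ(1 − e^(−t/τᵢ)),

with 0 ≤ gᵢ, Σgᵢ < 1, τᵢ > 0.  Parameter tables report decay constants
βᵢ = 1/τᵢ (s⁻¹); the code stores τᵢ and converts on input/output.  The
scalar (rather than full tensorial deviatoric) convolution is the standard
identification idealisation for homogeneous tests and is exact for the
rate-independent kinematics used here.

Two independent evaluators are implemented:

1. **Recursive integrator** (production path): for each Prony term the
   relaxed overstress qᵢ(t) = gᵢ∫₀ᵗ e^(−(t−s)/τᵢ) σᵉ′(s) ds satisfies, on a
   uniform grid with step Δt,
   qᵢⁿ⁺¹ = e^(−Δt/τᵢ) qᵢⁿ + gᵢ (τᵢ/Δt)(1 − e^(−Δt/τᵢ)) (σᵉₙ₊₁ − σᵉₙ),
   and σₙ = (1 − Σgᵢ) σᵉₙ + Σᵢ qᵢⁿ.  This is the exact hereditary integral
   for σᵉ piecewise linear in time (the classical internal-variable
   exponential integrator); it is O(N) and implemented as a first-order IIR
   filter.  Both limits are built in: Δt ≪ τ gives the instantaneous
   response, Δt ≫ τ the long-term response scaled by 1 − Σgᵢ.
2. **Trapezoidal quadrature oracle** (testing only): integrating the
   convolution by parts (σᵉ(0) = 0) gives
   σ(t) = σᵉ(t) + ∫₀ᵗ ġ_R(t−s) σᵉ(s) ds with ġ_R analytic, evaluated by the
   trapezoidal rule on a refined grid — O(N²), free of numerical
   differentiation, exact in the elastic limit, and discretised completely
   differently from the recursion.  The two must agree within 0.5% of peak
   stress at 1,000 steps; this dual route is the main guard against
   integrator bugs.

Loading histories are constant-rate ramps (the experimental protocol):
uniform time grid on [0, excursion/rate], 1,000 steps by default.  Default
maximum strains are γ_max = 8/7 ≈ 1.14 for the brain-shear design (the only
printed displacement is 8 mm on a 7-mm sample; high-rate tests ran to
failure with no strain recorded) and λ_max = 1.3 for the vessel design (a
pure default), both configurable.  Relaxation, creep, cyclic loading and
preconditioning histories are not modelled.

## Calibration

The fit targets per-rate *mean* curves (the reporting convention of the
source experiments), not pooled replicates.  Residuals are
wᶜ · (σ_model(strainₖ) − σ̄ₖ) with per-curve weight wᶜ = 1/max|σ̄ᶜ| by
default, because peak stresses differ by orders of magnitude across rates
and the high-rate curves would otherwise dominate; optional inverse-SEM
weighting exists.  The model curve is the recursive QLV solution of the
curve's declared ramp, linearly interpolated onto the data strain grid;
data beyond the simulated ramp raise rather than extrapolate.

Optimisation is scipy's bounded trust-region-reflective least squares on
the transformed parameter vector [log₁₀μᵢ, |αᵢ|, gᵢ, log₁₀βᵢ] (log scales
for the positive, decade-spanning parameters), with bounds
μ ∈ [10⁻⁴, 10⁶] kPa, |α| ∈ [0.1, 50], g ∈ [0, 0.999], β ∈ [10⁻⁴, 10⁴] s⁻¹.
Because the loss surface is multi-modal, the fit restarts from 16 seeded
random initial points (log-uniform in μ and β, uniform in |α| and g;
default seed 0) and keeps the lowest converged cost, ties broken by lowest
start index — making the whole procedure deterministic given data, config
and seed.  α is restricted to positive values by default (all single-term
reference tissues have α > 0); fixed per-term signs can be supplied for
two-term fits with a negative exponent.  Multi-term fits sort Ogden terms
by descending μ and Prony terms by ascending τ so that permutation-
equivalent optima report identically; a soft penalty keeps Σgᵢ < 1.
Identifiability of (g, τ) requires curves at ≥ 2 distinct rates; a
single-rate fit with Prony terms warns and records the warning in the
result.

Goodness of fit is R² = 1 − SS_res/SS_tot per curve (SS_tot about the data
mean; undefined for constant curves) plus a pooled R² over all points.
Parameter uncertainty is estimated by within-rate bootstrap of replicates
(resample, re-summarise, refit; percentile intervals; deterministic given
seed).  With n = 6 replicates and 16–50 resamples the percentile intervals
are approximate — empirical coverage of the 95% interval is below nominal
(roughly 60–80% for μ in internal simulation studies) — so they should be
read as scale estimates, not exact frequentist intervals.

## Synthetic data

The generator emulates the experimental design — three rates
(0.01, 150, 300 s⁻¹); n = 6 replicates per rate for the three brain
regions in shear, n = 12 for arteries in tension; mean ± SEM summaries —
with Gaussian noise sd = a·|σ_true| + b around the true QLV curve,
independent across points and replicates.  Defaults a = 0.05 and
b = 1% of peak stress give SEM bars of the visual scale seen in such
experiments.  Replicates share one 101-point strain grid per rate.  What
the generator does *not* emulate: sample-to-sample geometry and stiffness
variation (replicates scatter around one true curve), heteroscedastic
point-to-point correlation, preconditioning effects and failure-point
censoring of high-rate tests.  Passing recovery tests therefore
demonstrates identifiability of the model under the stated noise law, not
robustness to structured biological variability.

## Numerical choices and conventions

- Units: curves in kPa and s; material cards in SI (Pa, s; conversions
  kPa→Pa and GPa→Pa centralised in the card writer and logged).  Densities
  kg/m³; bulk and elastic moduli in GPa in tables.
- Forward-model discretisation: 1,000 uniform steps per ramp (halving the
  step changes peak stress by ≪ 0.25% for every reference tissue at every
  protocol rate).
- Curve files: two CSV dialects (per-observation `long`, per-point mean/SEM
  `summary`), 9-significant-digit formatting, deterministic row order, so
  writers are byte-reproducible.
- Material cards: a documented generic FE dialect (Ogden line (μᵢ[Pa], αᵢ, 0)
  with 0 as incompressibility placeholder; Prony line (gᵢ, 0, τᵢ[s]));
  parse/render round-trips at 6 significant digits.  Not byte-compatible
  with any commercial solver.
- Reference presets: six materials (cerebrum, cerebellum, brainstem,
  vasculature, dura, skull); the skull is linear-elastic metadata
  (E = 2.00 GPa, ν = 0.22) and is exported as an elastic card.  A two-term
  Ogden soft-tissue model is supported generically but not shipped as a
  preset because the published two-term column pairing is ambiguous; users
  supply their own (μᵢ, αᵢ) mapping.

## Problem sizes used in validation

Round-trip recovery runs 3×1,001-point noiseless curves per material with
the default 16-start fit (a few seconds per material).  The noisy-pipeline
study uses the full experimental design (n = 6, three rates, 101-point
grids) over 20 generator seeds; the bootstrap checks use reduced
configurations (3–4 starts, 200–300 forward steps, 16 resamples) since they
probe calibration of the machinery rather than accuracy limits.

## Known limitations

- QLV with a single Prony term cannot represent relaxation spectra broader
  than one decade; multi-term series are supported but identifiability from
  three-rate monotone ramps degrades quickly.
- With g close to 1 (cerebrum, brainstem: g = 0.99) the long-term modulus
  is 1% of the instantaneous one; the low-rate curve then carries most of
  the information about g and β, and noise on it inflates their variance.
- The recursive integrator requires uniform time grids; non-uniform
  histories must be resampled first.
- Fitted parameters are conditional on the chosen stress measure and on the
  assumed constant-rate ramp; neither choice can be recovered from data
  after the fact.
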