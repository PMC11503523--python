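# Methods

This note documents the models, numerical choices and synthetic-data
design behind `metallospec`, and what the test suite does and does not
demonstrate.

## Equilibrium model and conventions

Components are the independent building blocks (H⁺, the ligand, metal
cations); every species M_pL_qH_r is formed from free components with an
overall constant log β_pqr. Conventions:

- **Hydroxide is not a component.** Hydroxo species use a proton
  coefficient r = −1, so their β values are negative logs (a proton is
  released), and OH⁻ enters the proton mass balance as −K_w/[H⁺]. This
  matches the convention of the tabulated constants (e.g. −5.55 for
  [Mn(GMT)OH]⁺ at 45 °C).
- **Concentration quotients.** Constants are valid at the stated ionic
  strength (0.1 mol L⁻¹ NaCl); no Debye–Hückel/SIT correction is applied
  anywhere, because the source constants were never extrapolated to zero
  ionic strength.
- **pK_w and hydrolysis constants are editable inputs.** The shipped model
  files carry pK_w = 13.97 / 13.38 / 13.02 at 25 / 37 / 45 °C and a
  van't Hoff-style extrapolation (14.49) at 15 °C, plus single-temperature
  literature hydrolysis constants (log β: MnOH −10.59, ZnOH −8.96,
  CaOH −12.78) reused at all temperatures. All are flagged in the files'
  `notes` fields; replace them when better values are at hand.
- **Overall-β reading of the constants.** The mixed species constants are
  interpreted as overall M + L + H ⇌ MLH formation constants. Under this
  convention the computed [Mn(GMT)H]³⁺ maximum at 1 mmol L⁻¹ is ≈64%, not
  the ≈98% a stepwise M + HL reading would give; published percentage
  maxima are therefore treated as convention-ambiguous and never asserted.
- **Formation percentages** are reported relative to a user-chosen
  reference component (the ligand by default); the free reference appears
  as one of the curves, so percentages sum to exactly 100 by mass balance.

## Speciation solver

Unknowns are log free concentrations (positivity for free), iterated with
damped Newton on the mass-balance residuals using the analytic Jacobian
x_jδ_jk + Σ_s ν_sj ν_sk c_s (+K_w/[H] on the proton diagonal). Steps are
capped at ~3 decades per component and halved (up to 40 times) whenever
the scaled residual norm would grow. Residuals are scaled by the "gross
turnover" max(|T_j|, x_j + Σ|ν|c + [OH]) so convergence (default 10⁻¹²,
guaranteed ≤10⁻¹⁰) is meaningful even when the analytical proton total
passes through zero mid-titration. Failed starts fall back to a ladder of
proton initialisations (10⁻², …, 10⁻¹¹); along titrations and pH grids the
previous point warm-starts the next. Fixing the pH removes H from the
unknowns by folding [H⁺] into effective constants.

## Titration forward models

Dilution: totals scale by V₀/(V₀+v); the titrant adds (HCl) or subtracts
(NaOH) from the analytical proton total, which may go negative. The
electrode reads E⁰ + s·log₁₀[H⁺] + j_a[H⁺] + j_b[OH⁻]; the junction form
j_a[H]+j_b[OH] is the standard BSTAC parametrisation (the source analysis
names a junction potential but no formula), with j_a = j_b = 0 defaults.
The Nernst slope defaults to RT ln10/F at the design temperature and is
refinable, since whether the original analysis refined it is unstated.
Spectra are net (blank-subtracted) Beer–Lambert superpositions; NMR shifts
are fast-exchange mole-fraction averages over ligand environments. Only
equilibrium observables are modelled: no electrode drift, CO₂ ingress,
slow-exchange lineshapes or raw-FID processing.

## Refinement

Levenberg–Marquardt (scipy `least_squares`, method `lm`) on weighted
residuals; finite-difference Jacobians for the constants with relative
step 10⁻⁴; convergence on the scaled parameter step (10⁻⁸). Weights:

- emf: w = 1/(σ_E² + (dE/dv)²σ_v²) with σ_E = 0.15 mV, σ_v = 0.002 mL and
  the slope taken from the observed curve — points on the equivalence jump,
  where volume error masquerades as emf error, are down-weighted;
- absorbance and shifts: uniform 1/σ² with configurable σ.

Multiple datasets share log β but keep per-titration E⁰ (and optional
slope, junction and concentration corrections). Standard deviations come
from the linearised covariance scaled by the weighted RMS σ_fit; with
weights matching the generator's noise, σ_fit ≈ 1. Rank deficiency is
detected on the Jacobian's singular values (ratio < 10⁻¹⁰) and the
offending parameters are flagged rather than silently pinned.

Spectral and NMR refinements are separable (variable projection): for each
trial set of constants the speciation is solved and the linear parameters
(ε per wavelength, δ per nucleus) are obtained by unconstrained linear
least squares. The inner solve is deliberately *not* sign-constrained —
clipping inside the objective biases the constants — and negative molar
absorptivities (noise at band tails) are clipped only in the final report,
with a diagnostic.

**Model selection** refines each candidate species set and ranks
lexicographically: a larger model displaces a smaller one only if it cuts
σ_fit by more than a configurable margin (default 20%), and any candidate
containing a species whose maximum formation percentage over the
experimental pH window stays below a floor (default 5%) is rejected. Both
rules matter in practice: a spurious ML species typically fails the floor
*and* buys no σ_fit improvement, while dropping a real hydroxo complex
inflates σ_fit severalfold.

## Thermodynamics

Stepwise constants are differences of overall constants (MLH minus ligand
protonation for the M + HL route; MLOH minus metal hydrolysis for the
MOH + L route); the stepwise interpretation of the tabulated ΔG values is
confirmed by exact −Rθ ln10·log K matches (e.g. 4.04 → −23.1, 2.79 →
−15.9, 3.19 → −18.2 kJ mol⁻¹). The van't Hoff fit is the two-parameter
linear form (ΔH temperature-independent; no ΔC_p term — the four-point
temperature series cannot support one), weighted by 1/SD² when SDs are
supplied and unweighted otherwise; parameter SDs use the reduced
chi-square when degrees of freedom remain. Energies are kJ mol⁻¹,
temperatures kelvin internally. The hydroxo-route stepwise enthalpies are
not re-derived because they would need hydrolysis enthalpies that are
model inputs here; the tabulated triples are instead checked for
ΔG = ΔH − TΔS closure.

## Synthetic data

The generator emulates the study's designs: 25 mL initial volume, 10 mmol
L⁻¹ HCl carrying the pH-2 start, 0.1 mol L⁻¹ NaOH dosed in 64 steps to
~4% past the proton equivalence (pH ≈ 10.5), and the tabulated analytical
concentrations per scenario (e.g. 0.5/0.5 mmol L⁻¹ for the 1:1
potentiometric row, 0.06 mmol L⁻¹ for the spectrophotometric acid–base
row, 5 mmol L⁻¹ for NMR). Noise is i.i.d. Gaussian: 0.15 mV on emf and
0.002 mL on the *delivered* volumes (applied before the equilibrium solve,
while the recorded abscissa stays nominal — the same error structure the
refinement weights assume), 0.002 absorbance units and 0.002 ppm as
nominal spectral/NMR floors. pH in spectrophotometric and NMR datasets is
treated as measured without error, mirroring co-recorded calibrated-
electrode readings. One `numpy` Generator per campaign makes a seed fully
reproducible.

Spectral band shapes are synthetic: Gaussians anchored to the published
maxima (14 000 L mol⁻¹ cm⁻¹ at 280 nm protonated, 9 500 at 275 nm
neutral) with the protonated band's width solved so the two cross exactly
at the 260 nm isosbestic point; metal-complex bands are mildly
hyperchromic variants. The shift table anchors the seven observed proton
signals (3.8–7.9 ppm) with the 0.2 ppm deprotonation upfield shift on
CH-5′/CH-6′ and a nominal 0.02 ppm on the sugar protons; metal species sit
a synthetic 0.05 ppm downfield. Consequently, passing recovery tests show
that the estimators are correct and correctly calibrated *under the
assumed noise model*; they say nothing about electrode drift, baseline
error, band-shape misspecification or other systematics in real spectra.

## RDF stage

Minimum-image distances in a cubic periodic box; g(r) is the pair histogram
over frames normalised by the ideal-gas shell expectation, r_max ≤ L/2
enforced. The running coordination number is the cumulative neighbour
count per central atom (identical to 4πρ_B∫g r²dr on the same bins), and
first-shell numbers use the first local minimum of a 5-point-smoothed g(r)
after the first maximum (default bin 0.05 Å). The XYZ dialect is
frame-per-block with the box edge on the comment line (`box=16.85`). The
package analyses supplied trajectories only — it runs no dynamics — and
published peak positions from cluster-scale simulations are treated as
qualitative references.

## Problem sizes

Defaults keep every analysis in seconds on one core: 64-point titrations,
126-wavelength spectra on 25 pH points, 33-point NMR curves, and RDF
fixtures of a few hundred atoms × ≤8 frames. The statistical tests use 4
replicates for recovery, 20 seeds for SD calibration and 1/4/16 replicates
for consistency.

## Known limitations

- No activity-coefficient model: constants apply at 0.1 mol L⁻¹ only.
- ΔH is assumed temperature-independent over 15–45 °C.
- The hydroxo complexes' UV identifiability is weak when their band shapes
  resemble the free ligand's (reflected honestly in large reported SDs).
- Hydrolysis constants and pK_w are literature defaults, not refined.
- The acid-region amine (pK 3.60) titrates jointly with the mineral acid:
  potentiometric information about it comes from curve shape, not from a
  separate equivalence jump.
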