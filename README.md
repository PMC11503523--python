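# metallospec

Solution-equilibrium analysis for metal–ligand complexation studies:
chemical speciation solving, forward models for potentiometric, UV–vis and
¹H NMR titrations, weighted nonlinear refinement of formation constants,
speciation-model selection, van't Hoff thermodynamics, and solvation-shell
radial distribution functions on periodic trajectories.

The package grew out of a speciation study of the chemotherapeutic
gemcitabine (GMT, 2′-deoxy-2′,2′-difluorocytidine) with the biorelevant
cations Mn²⁺, Zn²⁺ and Ca²⁺: choosing conditions of temperature, pH and
metal-to-drug ratio that maximise complex formation requires knowing, at
each temperature, which species form and how strongly. It is aimed at
solution chemists who refine stability constants from titration data — the
workflow traditionally spread over BSTAC/STACO, HypSpec, HypNMR, HySS and
LIANA — and who want that workflow as one scriptable, testable library.

## The model

A speciation model is a set of components (H⁺, the ligand L, a metal M)
and species M<sub>p</sub>L<sub>q</sub>H<sub>r</sub> governed by mass-action
equilibria with overall formation constants

```
β_pqr = [MpLqHr] / ([M]^p [L]^q [H]^r)
```

reported as log₁₀ β at fixed ionic strength (0.1 mol L⁻¹ NaCl here, no
activity corrections). Hydroxo species carry r = −1 — e.g.
M²⁺ + L + H₂O ⇌ [M(L)OH]⁺ + H⁺ — and water enters through pK_w. Free
concentrations at given analytical totals come from damped Newton
iteration on the mass balances in log space; a titration is then a
sequence of such solves with dilution bookkeeping, observed through

* **emf**: E = E⁰ + s·log₁₀[H⁺] + j_a[H⁺] + j_b[OH⁻]  (glass electrode),
* **absorbance**: A(λ) = l·Σᵢ εᵢ(λ)·cᵢ  (Beer–Lambert superposition),
* **chemical shift**: δ_obs = Σᵢ xᵢ·δᵢ  (fast exchange, ligand mole
  fractions xᵢ).

Constants are refined by Levenberg–Marquardt on weighted residuals, with
emf weights propagating the instrument variances through the local curve
slope, w = 1/(σ_E² + (dE/dv)²σ_v²), and with molar absorptivities and
species shifts handled as separable linear parameters. Temperature series
of constants yield ΔH via van't Hoff,

```
log β(T) = log β_θ − (ΔH / R ln10) (1/T − 1/θ),   θ = 298.15 K,
```

and ΔG = −Rθ ln10 · log β_θ, TΔS = ΔH − ΔG.

Because no raw titration data are deposited anywhere, the package ships a
seeded synthetic-data generator reproducing the study's experimental
designs (25 mL samples, 0.02–6 mmol L⁻¹, pH 2–10, emf σ = 0.15 mV, volume
σ = 0.002 mL) so that every stage — solving, simulation, refinement,
selection, thermodynamics — is exercised end to end without downloads.

## Worked example

Refine the two Zn²⁺–GMT formation constants from four synthetic 1:1
potentiometric titrations at 45 °C, then locate the hydroxo complex's
formation maximum:

```python
import numpy as np
from metallospec import (NoiseSpec, RefinementSpec, distribution_curve,
                         fixture_model, generate_campaign, refine)

model = fixture_model("zn_gmt_45C")          # log β: 7.63, −4.40 (+ HL, ZnOH)
dss = generate_campaign("potentiometry 1:1", model, NoiseSpec(seed=42), replicates=4)
res = refine(dss, model.with_log_betas({"Zn(GMT)H": 7.0, "Zn(GMT)OH": -5.0}),
             RefinementSpec(["log_beta:Zn(GMT)H", "log_beta:Zn(GMT)OH", "E0:*"]))
print("converged:", res.converged, " sigma_fit: %.3f" % res.sigma_fit)
for tok in ("log_beta:Zn(GMT)H", "log_beta:Zn(GMT)OH"):
    print(f"{tok}: {res.values[tok]:.3f} +/- {res.sd[tok]:.3f}")

curve = distribution_curve(model, {"Zn": 1e-3, "GMT": 1e-3},
                           np.arange(2.0, 10.01, 0.5), "GMT")
i = curve.labels.index("Zn(GMT)OH")
j = int(np.argmax(curve.percent[:, i]))
print(f"Zn(GMT)OH max: {curve.percent[j, i]:.1f}% at pH {curve.pH[j]}")
```

prints (seed 42):

```
converged: True  sigma_fit: 0.908
log_beta:Zn(GMT)H: 7.645 +/- 0.013
log_beta:Zn(GMT)OH: -4.414 +/- 0.016
Zn(GMT)OH max: 84.1% at pH 10.0
```

Both generating constants are recovered within ~1 standard deviation and
the weighted RMS is ≈1, i.e. the fit is noise-limited. The same work runs
from the shell:

```sh
metallospec simulate --model src/metallospec/data/zn_gmt_45C.json \
    --scenario "potentiometry 1:1" --replicates 4 --seed 42 -o sim/
metallospec refine sim/*.csv --model src/metallospec/data/zn_gmt_45C.json \
    --free "log_beta:Zn(GMT)H" --free "log_beta:Zn(GMT)OH" --free "E0:*" \
    -o result.json
metallospec speciate src/metallospec/data/zn_gmt_45C.json \
    --total Zn=1e-3 --total GMT=1e-3 -o distribution.csv
```

A van't Hoff fit of the four tabulated protonation constants
(`metallospec thermo constants.csv --unweighted -o thermo.json`) prints
`dH = -22.4 kJ/mol`, inside the reported −20 ± 8 kJ mol⁻¹, and
`metallospec rdf traj.xyz --sel-a Mn --sel-b O -o rdf.csv` computes g(r)
and running coordination numbers from an XYZ trajectory with a cubic
periodic box.

## Layout

- `metallospec.model` / `metallospec.equilibrium` — model containers,
  speciation solver, distribution diagrams
- `metallospec.titration` — forward models for the three observables
- `metallospec.refine` — weighted LM refinement and model selection
- `metallospec.thermo` — stepwise constants, van't Hoff, ΔG/ΔH/TΔS
- `metallospec.synthetic` — seeded campaign generator and spectral/NMR
  fixtures
- `metallospec.rdf` — periodic-box radial distribution functions
- `metallospec.io` / `metallospec.cli` — interchange formats and the
  `metallospec` command
- `src/metallospec/data/` — model files encoding the determined constants
  per temperature (hydrolysis constants and pK_w flagged as literature
  defaults)

See `docs/methods.md` for the numerical methods, the synthetic-data
design, and known limitations.
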