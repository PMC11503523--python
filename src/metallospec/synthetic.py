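"""Seeded synthetic titration campaigns.

Emulates the study conditions of the three experiment families
(potentiometry, UV-vis spectrophotometry, 1H NMR) on gemcitabine (GMT) and
its Mn2+/Zn2+/Ca2+ systems: 25 mL starting volume, mineral acid carrying
the start of the pH 2-10 window, NaOH titrant, and instrument noise of
0.15 mV on emf and 0.002 mL on delivered volumes.  Scenario identifiers
name a technique and metal-to-ligand ratio and resolve to the tabulated
analytical concentrations (mmol/L):

================  ==========  =======  =======
scenario          technique   C_M      C_GMT
================  ==========  =======  =======
acid-base         pot.        --       0.5
1:1               pot.        0.5      0.5
1:1.5             pot.        0.5      0.75
1:2               pot.        0.5      1
2:1               pot.        1        0.5
acid-base         spec.       --       0.06
1:2               spec.       0.02     0.04
1:1.4             spec.       0.035    0.05
1:4               spec.       0.02     0.08
1:1               spec.       0.04     0.04
acid-base         NMR         --       5
1.2:1             NMR         6        5
================  ==========  =======  =======

The spectral band shapes and the full shift table are synthetic fixtures:
only the published anchor points (band maxima 14 000 L mol-1 cm-1 at
280 nm for the protonated and 9 500 at 275 nm for the neutral form, the
260 nm isosbestic crossing, the seven proton signals and the 0.2 ppm
deprotonation upfield shift) are imposed; everything in between is a
smooth Gaussian interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .model import EquilibriumModel
from .titration import (
    PotentiometricCalibration,
    ShiftTable,
    SpectralProfile,
    TitrationDataset,
    TitrationDesign,
    simulate_potentiometric,
    simulate_shifts,
    simulate_spectra,
)

__all__ = [
    "NoiseSpec",
    "resolve_scenario",
    "generate_campaign",
    "fixture_spectral_profile",
    "fixture_shift_table",
]


@dataclass
class NoiseSpec:
    """I.i.d. Gaussian instrument noise levels and the RNG seed."""

    emf_sd: float = 0.15  # mV
    volume_sd: float = 0.002  # mL
    abs_sd: float = 0.002  # absorbance units
    shift_sd: float = 0.002  # ppm
    seed: int = 0

    def __post_init__(self):
        for f in ("emf_sd", "volume_sd", "abs_sd", "shift_sd"):
            if getattr(self, f) < 0:
                raise UsageError(f"{f} must be >= 0")

    def zeroed(self) -> "NoiseSpec":
        return NoiseSpec(0.0, 0.0, 0.0, 0.0, self.seed)


# mmol/L per the experimental-conditions table
_SCENARIOS: dict[tuple[str, str], tuple[float | None, float]] = {
    ("potentiometry", "acid-base"): (None, 0.5),
    ("potentiometry", "1:1"): (0.5, 0.5),
    ("potentiometry", "1:1.5"): (0.5, 0.75),
    ("potentiometry", "1:2"): (0.5, 1.0),
    ("potentiometry", "2:1"): (1.0, 0.5),
    ("spectrophotometry", "acid-base"): (None, 0.06),
    ("spectrophotometry", "1:2"): (0.02, 0.04),
    ("spectrophotometry", "1:1.4"): (0.035, 0.05),
    ("spectrophotometry", "1:4"): (0.02, 0.08),
    ("spectrophotometry", "1:1"): (0.04, 0.04),
    ("nmr", "acid-base"): (None, 5.0),
    ("nmr", "1.2:1"): (6.0, 5.0),
}

_TECH_ALIASES = {
    "potentiometry": "potentiometry",
    "pot": "potentiometry",
    "spectrophotometry": "spectrophotometry",
    "uv": "spectrophotometry",
    "nmr": "nmr",
}


def resolve_scenario(scenario: str) -> dict:
    """Parse e.g. ``"potentiometry 1:1"`` into technique + concentrations (mol/L)."""
    parts = scenario.split()
    if len(parts) != 2 or parts[0].lower() not in _TECH_ALIASES:
        raise UsageError(
            f"scenario {scenario!r} not understood; expected '<technique> <ratio>'"
        )
    tech = _TECH_ALIASES[parts[0].lower()]
    key = (tech, parts[1])
    if key not in _SCENARIOS:
        raise UsageError(f"no tabulated conditions for scenario {scenario!r}")
    c_m, c_l = _SCENARIOS[key]
    return {
        "technique": tech,
        "C_M": None if c_m is None else c_m * 1e-3,
        "C_GMT": c_l * 1e-3,
    }


def _metal_component(model: EquilibriumModel, ligand: str) -> str | None:
    others = [c.name for c in model.components if c.name not in ("H", ligand)]
    if len(others) > 1:
        raise UsageError(f"ambiguous metal component among {others}")
    return others[0] if others else None


def _potentiometric_design(
    composition: dict[str, float],
    temperature: float,
    *,
    initial_volume: float = 0.025,
    acid: float = 0.010,
    titrant_concentration: float = 0.1,
    n_points: int = 64,
) -> TitrationDesign:
    """25 mL of sample + 10 mmol/L HCl titrated with 0.1 M NaOH to pH ~10.5."""
    comp = dict(composition)
    comp["H"] = acid
    # dose past the mineral-acid equivalence with enough excess for pH > 10
    v_eq = acid * initial_volume / titrant_concentration
    v_max = 1.04 * v_eq
    additions = np.linspace(0.0, v_max, n_points)
    return TitrationDesign(
        initial_volume=initial_volume,
        initial_composition=comp,
        titrant="NaOH",
        titrant_concentration=titrant_concentration,
        additions=list(additions),
        temperature=temperature,
    )


def generate_campaign(
    scenario: str | TitrationDesign,
    model: EquilibriumModel,
    noise: NoiseSpec,
    replicates: int = 1,
    *,
    ligand: str = "GMT",
    calibration: PotentiometricCalibration | None = None,
    profile: SpectralProfile | None = None,
    shift_table: ShiftTable | None = None,
    pH_grid: np.ndarray | None = None,
) -> list[TitrationDataset]:
    """Generate seeded replicate datasets for one scenario.

    Noise is drawn from one ``numpy`` Generator seeded with ``noise.seed``,
    so the same seed reproduces the campaign bit-for-bit.  Volume noise
    perturbs the actually-delivered volumes *before* the equilibrium solve
    (the recorded abscissa stays nominal), emf/absorbance/shift noise is
    added to the simulated observable.  Provenance (truth constants, seed,
    scenario) rides along in each dataset's metadata.
    """
    if replicates < 1:
        raise UsageError("replicates must be >= 1")
    rng = np.random.default_rng(noise.seed)
    truth = {sp.label: sp.log_beta for sp in model.species}

    if isinstance(scenario, TitrationDesign):
        technique = "potentiometry"
        design0 = scenario
        scen_name = "explicit design"
    else:
        info = resolve_scenario(scenario)
        technique = info["technique"]
        scen_name = scenario
        composition = {ligand: info["C_GMT"]}
        metal = _metal_component(model, ligand)
        if info["C_M"] is not None:
            if metal is None:
                raise UsageError(
                    f"scenario {scenario!r} needs a metal but the model has none"
                )
            composition[metal] = info["C_M"]
        elif metal is not None:
            raise UsageError(
                f"scenario {scenario!r} is metal-free but the model declares {metal!r}"
            )
        design0 = None

    datasets: list[TitrationDataset] = []
    if technique == "potentiometry":
        if design0 is None:
            design0 = _potentiometric_design(composition, model.temperature)
        calib = calibration or PotentiometricCalibration(E0=400.0)
        nominal = np.asarray(design0.additions, dtype=float)
        for _ in range(replicates):
            delivered = nominal + rng.normal(0.0, noise.volume_sd * 1e-3, nominal.size)
            delivered = np.maximum(delivered, 0.0)
            _, emf = simulate_potentiometric(design0, model, calib, volumes=delivered)
            emf = emf + rng.normal(0.0, noise.emf_sd, emf.size)
            datasets.append(
                TitrationDataset(
                    kind="emf",
                    temperature=model.temperature,
                    design=design0,
                    calibration=calib,
                    volumes=nominal.copy(),
                    emf=emf,
                    metadata={
                        "truth_log_beta": dict(truth),
                        "seed": noise.seed,
                        "scenario": scen_name,
                        "E0_true": calib.E0,
                    },
                )
            )
    elif technique == "spectrophotometry":
        prof = profile or fixture_spectral_profile(model=model, ligand=ligand)
        grid = (
            np.arange(2.0, 8.0 + 1e-9, 0.25) if pH_grid is None else np.asarray(pH_grid)
        )
        clean = simulate_spectra(grid, model, composition, prof)
        for _ in range(replicates):
            noisy = clean + rng.normal(0.0, noise.abs_sd, clean.shape)
            datasets.append(
                TitrationDataset(
                    kind="absorbance",
                    temperature=model.temperature,
                    totals=dict(composition),
                    pH=grid.copy(),
                    wavelengths=prof.wavelengths.copy(),
                    absorbance=noisy,
                    path_length=prof.path_length,
                    metadata={
                        "truth_log_beta": dict(truth),
                        "seed": noise.seed,
                        "scenario": scen_name,
                    },
                )
            )
    else:  # nmr
        table = shift_table or fixture_shift_table(model=model, ligand=ligand)
        grid = (
            np.arange(2.0, 10.0 + 1e-9, 0.25) if pH_grid is None else np.asarray(pH_grid)
        )
        clean = simulate_shifts(grid, model, composition, table, ligand=ligand)
        for _ in range(replicates):
            noisy = clean + rng.normal(0.0, noise.shift_sd, clean.shape)
            datasets.append(
                TitrationDataset(
                    kind="shift",
                    temperature=model.temperature,
                    totals=dict(composition),
                    pH=grid.copy(),
                    nuclei=list(table.nuclei),
                    shifts=noisy,
                    metadata={
                        "truth_log_beta": dict(truth),
                        "seed": noise.seed,
                        "scenario": scen_name,
                    },
                )
            )
    return datasets


# ---------------------------------------------------------------------------
# spectral / NMR fixtures


def _gaussian_band(wl, center, width, height):
    return height * np.exp(-((wl - center) ** 2) / (2.0 * width**2))


def fixture_spectral_profile(
    wavelengths: np.ndarray | None = None,
    *,
    model: EquilibriumModel | None = None,
    ligand: str = "GMT",
    path_length: float = 1.0,
) -> SpectralProfile:
    """Synthetic Gaussian molar-absorptivity bands for the GMT chromophore.

    Anchors: the protonated form peaks at 280 nm / 14 000 L mol-1 cm-1, the
    neutral form at 275 nm / 9 500, and the two bands cross exactly at the
    260 nm isosbestic point (the protonated band's width is solved from
    that constraint).  Metal-complex bands, when a model is supplied, are
    synthetic variants: mildly hyperchromic and red-shifted for the
    protonated complex, hyperchromic for the hydroxo one.
    """
    wl = np.arange(225.0, 350.5, 1.0) if wavelengths is None else np.asarray(wavelengths)
    width_l = 18.0
    eps_l_260 = 9500.0 * np.exp(-((260.0 - 275.0) ** 2) / (2.0 * width_l**2))
    width_hl = np.sqrt((280.0 - 260.0) ** 2 / (2.0 * np.log(14000.0 / eps_l_260)))
    eps = {
        f"({ligand})H": _gaussian_band(wl, 280.0, width_hl, 14000.0),
        ligand: _gaussian_band(wl, 275.0, width_l, 9500.0),
    }
    if model is not None:
        for sp in model.species:
            if sp.coefficient(ligand) == 0 or sp.label in eps:
                continue
            if sp.coefficient("H") > 0:
                eps[sp.label] = _gaussian_band(wl, 282.0, width_hl, 15400.0)
            else:
                eps[sp.label] = _gaussian_band(wl, 277.0, width_l, 10450.0)
    return SpectralProfile(
        wavelengths=wl, epsilon=eps, path_length=path_length, chromophore=ligand
    )


_NUCLEI = ["CH2-a", "CH2-b", "CH-4", "CH-5", "CH-2", "CH-5p", "CH-6p"]
_SHIFT_HL = [3.80, 3.90, 4.10, 4.30, 6.10, 6.20, 7.90]
# 0.2 ppm upfield on the aromatic CH-5'/CH-6' upon amine deprotonation;
# a nominal 0.02 ppm on the sugar protons (synthetic choice)
_SHIFT_L = [3.78, 3.88, 4.08, 4.28, 6.08, 6.00, 7.70]


def fixture_shift_table(
    *, model: EquilibriumModel | None = None, ligand: str = "GMT"
) -> ShiftTable:
    """Synthetic per-species shift table anchored to the printed peak list.

    Free protonated ligand: the seven observed signals (3.8, 3.9, 4.1, 4.3,
    6.1, 6.2, 7.9 ppm); neutral ligand 0.2 ppm upfield on CH-5'/CH-6'.
    Metal complexes, when a model is supplied, sit a synthetic 0.05 ppm
    downfield of the matching free form (weak-interaction regime).
    """
    delta = {
        f"({ligand})H": dict(zip(_NUCLEI, _SHIFT_HL)),
        ligand: dict(zip(_NUCLEI, _SHIFT_L)),
    }
    if model is not None:
        for sp in model.species:
            if sp.coefficient(ligand) == 0 or sp.label in delta:
                continue
            base = _SHIFT_HL if sp.coefficient("H") > 0 else _SHIFT_L
            delta[sp.label] = dict(zip(_NUCLEI, [v + 0.05 for v in base]))
    return ShiftTable(nuclei=list(_NUCLEI), delta=delta)
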