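"""Forward models for the three titration observables.

Potentiometry: a glass electrode reads

    E = E0 + s * log10[H+] + j_a [H+] + j_b [OH-]

with s the Nernst slope and j_a, j_b liquid-junction coefficients.  Along a
titration, analytical totals are diluted by V0/(V0+v) and the titrant adds
to (HCl) or subtracts from (NaOH) the proton total.

Spectrophotometry: Beer-Lambert superposition of the absorbing species,
Abs(lambda) = l * sum_i eps_i(lambda) c_i.

NMR: under fast mutual exchange on the NMR time scale the observed shift of
each nucleus is the mole-fraction average of the species shifts over the
ligand distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .equilibrium import solve_state
from .errors import ConvergenceError, UsageError
from .model import EquilibriumModel

__all__ = [
    "TitrationDesign",
    "PotentiometricCalibration",
    "SpectralProfile",
    "ShiftTable",
    "TitrationDataset",
    "nernst_slope",
    "simulate_potentiometric",
    "simulate_spectra",
    "simulate_shifts",
    "ligand_mole_fractions",
]

GAS_CONSTANT = 8.314  # J K-1 mol-1
FARADAY = 96485.332  # C mol-1


def nernst_slope(temperature: float) -> float:
    """Theoretical electrode slope RT ln10 / F in mV per log10 unit."""
    return 1000.0 * GAS_CONSTANT * temperature * np.log(10.0) / FARADAY


@dataclass
class TitrationDesign:
    """Composition and dosing plan of one potentiometric titration.

    ``initial_composition`` holds analytical concentrations (mol/L) per
    component of the attached model; its ``"H"`` entry is the mineral-acid
    concentration (HCl here).  ``additions`` are cumulative titrant volumes
    in litres.
    """

    initial_volume: float  # L
    initial_composition: dict[str, float]
    titrant: str  # "NaOH" or "HCl"
    titrant_concentration: float  # mol/L
    additions: list[float]  # cumulative, L
    temperature: float  # K

    def __post_init__(self):
        if self.initial_volume <= 0:
            raise UsageError("initial volume must be positive")
        if self.titrant not in ("NaOH", "HCl"):
            raise UsageError("titrant must be 'NaOH' or 'HCl'")
        if self.titrant_concentration <= 0:
            raise UsageError("titrant concentration must be positive")
        v = np.asarray(self.additions, dtype=float)
        if v.size and np.any(np.diff(v) <= 0):
            raise UsageError("cumulative addition volumes must be strictly increasing")
        for k, c in self.initial_composition.items():
            if k != "H" and c <= 0:
                raise UsageError(f"initial concentration of {k!r} must be positive")

    def totals_at(self, volume: float) -> dict[str, float]:
        """Diluted analytical totals after ``volume`` L of titrant."""
        v0 = self.initial_volume
        dil = v0 / (v0 + volume)
        totals = {k: c * dil for k, c in self.initial_composition.items()}
        sign = -1.0 if self.titrant == "NaOH" else 1.0
        totals["H"] = (
            self.initial_composition.get("H", 0.0) * v0
            + sign * self.titrant_concentration * volume
        ) / (v0 + volume)
        return totals


@dataclass
class PotentiometricCalibration:
    """Electrode calibration: E0, Nernst slope and junction coefficients.

    Junction potential is modelled as ``j_a [H+] + j_b [OH-]`` (mV L/mol),
    zero by default.
    """

    E0: float  # mV
    nernst: float | None = None  # mV/decade; None = theoretical at use time
    junction_acid: float = 0.0  # mV L mol-1
    junction_base: float = 0.0  # mV L mol-1

    def slope_at(self, temperature: float) -> float:
        s = nernst_slope(temperature) if self.nernst is None else self.nernst
        if s <= 0:
            raise UsageError("Nernst slope must be positive")
        return s

    def emf(self, h: float, kw: float, temperature: float) -> float:
        s = self.slope_at(temperature)
        return (
            self.E0
            + s * np.log10(h)
            + self.junction_acid * h
            + self.junction_base * kw / h
        )


@dataclass
class SpectralProfile:
    """Per-species molar absorptivities on a wavelength grid.

    ``epsilon`` maps a species label (or a free-component name, for the
    unbound chromophore) to an array of molar absorptivities (L mol-1 cm-1)
    on ``wavelengths`` (nm).  ``chromophore`` names the light-absorbing
    component: every species containing it must have an epsilon entry.
    """

    wavelengths: np.ndarray  # nm
    epsilon: dict[str, np.ndarray]
    path_length: float = 1.0  # cm
    chromophore: str = "GMT"

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise UsageError("wavelength grid must be strictly increasing")
        for lab, eps in self.epsilon.items():
            arr = np.asarray(eps, dtype=float)
            if arr.shape != self.wavelengths.shape:
                raise UsageError(f"epsilon for {lab!r} does not match the grid")
            if np.any(arr < 0):
                raise UsageError(f"epsilon for {lab!r} must be nonnegative")
            self.epsilon[lab] = arr


@dataclass
class ShiftTable:
    """Species chemical shifts per nucleus (ppm) for fast-exchange averaging.

    ``delta[label][nucleus]`` is the intrinsic shift of the given ligand
    environment; the table must cover every ligand-containing species plus
    the free ligand.
    """

    nuclei: list[str]
    delta: dict[str, dict[str, float]]

    def __post_init__(self):
        for lab, per in self.delta.items():
            for nuc in self.nuclei:
                if nuc not in per:
                    raise UsageError(f"shift table lacks {nuc!r} for {lab!r}")
                if not np.isfinite(per[nuc]):
                    raise UsageError(f"non-finite shift for {lab!r}/{nuc!r}")


@dataclass
class TitrationDataset:
    """One experiment's design plus its observed signals.

    ``kind`` selects which observation arrays are populated:

    - ``"emf"``: ``volumes`` (L) and ``emf`` (mV), with ``design`` and
      ``calibration`` attached;
    - ``"absorbance"``: ``pH``, ``wavelengths`` (nm) and ``absorbance``
      (n_pH x n_wavelength), at fixed ``totals``;
    - ``"shift"``: ``pH``, ``nuclei`` and ``shifts`` (n_pH x n_nuclei), at
      fixed ``totals``.

    ``metadata`` carries provenance (generator truth, seed, scenario).
    """

    kind: str
    temperature: float
    design: TitrationDesign | None = None
    calibration: PotentiometricCalibration | None = None
    volumes: np.ndarray | None = None
    emf: np.ndarray | None = None
    totals: dict[str, float] | None = None
    pH: np.ndarray | None = None
    wavelengths: np.ndarray | None = None
    absorbance: np.ndarray | None = None
    nuclei: list[str] | None = None
    shifts: np.ndarray | None = None
    path_length: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("emf", "absorbance", "shift"):
            raise UsageError(f"unknown dataset kind {self.kind!r}")

    @property
    def n_observations(self) -> int:
        if self.kind == "emf":
            return len(self.emf)
        if self.kind == "absorbance":
            return self.absorbance.size
        return self.shifts.size


# ---------------------------------------------------------------------------
# forward models


def simulate_potentiometric(
    design: TitrationDesign,
    model: EquilibriumModel,
    calib: PotentiometricCalibration,
    *,
    volumes: Sequence[float] | None = None,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate emf (mV) at each cumulative titrant volume.

    Returns ``(volumes, emf)``.  ``volumes`` overrides the design's dosing
    plan (used when actually-delivered volumes differ from nominal ones).
    """
    if abs(design.temperature - model.temperature) > 1e-9:
        raise UsageError(
            f"design temperature {design.temperature} K != model {model.temperature} K"
        )
    v = np.asarray(design.additions if volumes is None else volumes, dtype=float)
    kw = 10.0 ** (-model.pKw)
    emf = np.empty(v.size)
    warm = None
    names = model.component_names
    for i, vol in enumerate(v):
        totals = design.totals_at(vol)
        try:
            st = solve_state(model, totals, tol=tol, initial_free=warm)
        except ConvergenceError as exc:
            exc.context = {"addition_index": i, "volume_L": float(vol)}
            raise
        warm = {nm: st.free_concentrations[nm] for nm in names}
        emf[i] = calib.emf(st.free_concentrations["H"], kw, design.temperature)
    return v, emf


def _species_concentration_matrix(pH_list, model, totals, labels, tol=1e-12):
    """(n_pH, n_labels) concentrations; a component name means its free form."""
    grid = np.asarray(pH_list, dtype=float)
    names = model.component_names
    out = np.empty((grid.size, len(labels)))
    warm = None
    for i, ph in enumerate(grid):
        st = solve_state(model, totals, fixed_pH=ph, tol=tol, initial_free=warm)
        warm = {nm: st.free_concentrations[nm] for nm in names if nm != "H"}
        for j, lab in enumerate(labels):
            if lab in st.species_concentrations:
                out[i, j] = st.species_concentrations[lab]
            else:
                out[i, j] = st.free_concentrations[lab]
    return out


def _chromophore_labels(model: EquilibriumModel, chromophore: str) -> list[str]:
    labs = [sp.label for sp in model.species if sp.coefficient(chromophore) != 0]
    return labs + [chromophore]


def simulate_spectra(
    pH_list: Sequence[float],
    model: EquilibriumModel,
    totals: Mapping[str, float],
    profile: SpectralProfile,
    *,
    tol: float = 1e-12,
) -> np.ndarray:
    """Absorbance matrix (n_pH x n_wavelength) by Beer-Lambert superposition."""
    if profile.chromophore not in model.component_names:
        raise UsageError(f"chromophore {profile.chromophore!r} not in model")
    labels = _chromophore_labels(model, profile.chromophore)
    missing = [lab for lab in labels if lab not in profile.epsilon]
    if missing:
        raise UsageError(f"missing molar absorptivities for species: {missing}")
    if totals[profile.chromophore] == 0:
        return np.zeros((len(pH_list), profile.wavelengths.size))
    C = _species_concentration_matrix(pH_list, model, totals, labels, tol)
    E = np.vstack([profile.epsilon[lab] for lab in labels])  # (n_labels, n_wl)
    # per-species stoichiometric multiplicity of the chromophore
    mult = np.array(
        [
            model.get_species(lab).coefficient(profile.chromophore)
            if lab != profile.chromophore
            else 1
            for lab in labels
        ],
        dtype=float,
    )
    return profile.path_length * (C * mult) @ E


def ligand_mole_fractions(
    pH_list: Sequence[float],
    model: EquilibriumModel,
    totals: Mapping[str, float],
    ligand: str,
    *,
    tol: float = 1e-12,
) -> tuple[list[str], np.ndarray]:
    """Mole fraction of the ligand residing in each environment, per pH.

    Returns the environment labels (ligand-containing species + free ligand)
    and an (n_pH, n_labels) matrix whose rows sum to 1.
    """
    labels = _chromophore_labels(model, ligand)
    C = _species_concentration_matrix(pH_list, model, totals, labels, tol)
    mult = np.array(
        [
            model.get_species(lab).coefficient(ligand) if lab != ligand else 1
            for lab in labels
        ],
        dtype=float,
    )
    X = C * mult / totals[ligand]
    return labels, X


def simulate_shifts(
    pH_list: Sequence[float],
    model: EquilibriumModel,
    totals: Mapping[str, float],
    shifts: ShiftTable,
    *,
    ligand: str = "GMT",
    tol: float = 1e-12,
) -> np.ndarray:
    """Observed fast-exchange shifts (n_pH x n_nuclei), mole-fraction averaged."""
    if ligand not in model.component_names:
        raise UsageError(f"ligand {ligand!r} not in model")
    labels, X = ligand_mole_fractions(pH_list, model, totals, ligand, tol=tol)
    missing = [lab for lab in labels if lab not in shifts.delta]
    if missing:
        raise UsageError(f"shift table lacks species: {missing}")
    D = np.array(
        [[shifts.delta[lab][nuc] for nuc in shifts.nuclei] for lab in labels]
    )
    return X @ D
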