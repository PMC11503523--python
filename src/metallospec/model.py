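"""Equilibrium model containers.

A model is a set of *components* (the independent building blocks of the
system: the proton H, the ligand, metal cations) and *species* formed from
them by mass-action equilibria.  Each species carries an overall formation
constant ``beta`` for the reaction assembling it from free components,

    p M + q L + r H  <=>  MpLqHr,      beta = [MpLqHr] / ([M]^p [L]^q [H]^r)

stored as log10.  Hydroxide is never a component: hydroxo species use a
proton coefficient of -1 and water autoprotolysis enters through ``pKw``,
so a mixed hydroxo complex M(L)OH has stoichiometry {M: 1, L: 1, H: -1}
and a negative log beta (a proton is released on formation).

Constants are concentration quotients valid at the stated ionic strength;
no activity-coefficient model is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import UsageError

__all__ = [
    "Component",
    "SpeciesDef",
    "EquilibriumModel",
    "load_model",
    "save_model",
]


@dataclass(frozen=True)
class Component:
    """An independent chemical component (e.g. ``H``, ``GMT``, ``Mn``)."""

    name: str
    charge: int = 0

    def __post_init__(self):
        if not self.name:
            raise UsageError("component name must be non-empty")


@dataclass(frozen=True)
class SpeciesDef:
    """One equilibrium species defined by component stoichiometry and log beta.

    Parameters
    ----------
    label
        Unique species label, e.g. ``"Mn(GMT)H"``.
    stoichiometry
        Signed integer coefficients per component name; an OH ligand is a
        proton coefficient of -1.
    log_beta
        log10 overall formation constant from free components.
    charge
        Optional; if given it must equal the stoichiometry-weighted sum of
        component charges (checked by the owning model).
    """

    label: str
    stoichiometry: Mapping[str, int]
    log_beta: float
    charge: int | None = None

    def __post_init__(self):
        stoich = dict(self.stoichiometry)
        if not stoich or all(v == 0 for v in stoich.values()):
            raise UsageError(f"species {self.label!r}: stoichiometry is all-zero")
        if not np.isfinite(self.log_beta):
            raise UsageError(f"species {self.label!r}: log_beta must be finite")
        object.__setattr__(self, "stoichiometry", stoich)

    def coefficient(self, component: str) -> int:
        return self.stoichiometry.get(component, 0)


@dataclass
class EquilibriumModel:
    """Components + species + medium conditions for one temperature.

    Attributes
    ----------
    components : list of Component
        Must include ``H``.
    species : list of SpeciesDef
    pKw : float
        log10 water ionic product (positive number, e.g. 13.97).
    temperature : float
        Kelvin.
    ionic_strength : float
        mol/L; a label only, no activity corrections are applied.
    """

    components: Sequence[Component]
    species: Sequence[SpeciesDef]
    pKw: float
    temperature: float
    ionic_strength: float = 0.1

    def __post_init__(self):
        self.components = list(self.components)
        self.species = list(self.species)
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise UsageError("component names must be unique")
        if "H" not in names:
            raise UsageError("'H' must be declared as a component")
        if not self.pKw > 0:
            raise UsageError("pKw must be positive")
        if not self.temperature > 0:
            raise UsageError("temperature must be positive kelvin")
        charges = {c.name: c.charge for c in self.components}
        labels = set()
        for sp in self.species:
            if sp.label in labels:
                raise UsageError(f"duplicate species label {sp.label!r}")
            labels.add(sp.label)
            for comp in sp.stoichiometry:
                if comp not in charges:
                    raise UsageError(
                        f"species {sp.label!r} references undeclared component {comp!r}"
                    )
            derived = sum(n * charges[c] for c, n in sp.stoichiometry.items())
            if sp.charge is not None and sp.charge != derived:
                raise UsageError(
                    f"species {sp.label!r}: declared charge {sp.charge} != "
                    f"stoichiometric charge {derived}"
                )

    # -- array views -------------------------------------------------------

    @property
    def component_names(self) -> list[str]:
        return [c.name for c in self.components]

    @property
    def species_labels(self) -> list[str]:
        return [s.label for s in self.species]

    def stoichiometry_matrix(self) -> np.ndarray:
        """(n_species, n_components) signed integer coefficient matrix."""
        names = self.component_names
        return np.array(
            [[sp.coefficient(n) for n in names] for sp in self.species],
            dtype=float,
        ).reshape(len(self.species), len(names))

    def log_betas(self) -> np.ndarray:
        return np.array([sp.log_beta for sp in self.species], dtype=float)

    # -- derived models ----------------------------------------------------

    def with_log_betas(self, updates: Mapping[str, float]) -> "EquilibriumModel":
        """Copy with some species' log beta replaced (labels must exist)."""
        unknown = set(updates) - set(self.species_labels)
        if unknown:
            raise UsageError(f"unknown species labels: {sorted(unknown)}")
        new_species = [
            replace(sp, log_beta=float(updates.get(sp.label, sp.log_beta)))
            for sp in self.species
        ]
        return replace(self, species=new_species)

    def subset(self, labels: Sequence[str]) -> "EquilibriumModel":
        """Copy retaining only the species whose labels are listed."""
        wanted = set(labels)
        unknown = wanted - set(self.species_labels)
        if unknown:
            raise UsageError(f"unknown species labels: {sorted(unknown)}")
        return replace(self, species=[s for s in self.species if s.label in wanted])

    def get_species(self, label: str) -> SpeciesDef:
        for sp in self.species:
            if sp.label == label:
                return sp
        raise UsageError(f"no species labelled {label!r}")


# -- JSON interchange ------------------------------------------------------


def _model_to_dict(model: EquilibriumModel) -> dict:
    return {
        "components": [{"name": c.name, "charge": c.charge} for c in model.components],
        "species": [
            {
                "label": s.label,
                "stoichiometry": dict(s.stoichiometry),
                "log_beta": s.log_beta,
            }
            for s in model.species
        ],
        "pKw": model.pKw,
        "temperature_K": model.temperature,
        "ionic_strength_M": model.ionic_strength,
    }


def _model_from_dict(doc: Mapping) -> EquilibriumModel:
    return EquilibriumModel(
        components=[Component(d["name"], int(d.get("charge", 0))) for d in doc["components"]],
        species=[
            SpeciesDef(
                label=d["label"],
                stoichiometry={k: int(v) for k, v in d["stoichiometry"].items()},
                log_beta=float(d["log_beta"]),
            )
            for d in doc["species"]
        ],
        pKw=float(doc["pKw"]),
        temperature=float(doc["temperature_K"]),
        ionic_strength=float(doc.get("ionic_strength_M", 0.1)),
    )


def fixture_model(name: str) -> EquilibriumModel:
    """Load one of the packaged model fixtures by name.

    Names look like ``"gmt_acid_base_25C"`` or ``"mn_gmt_45C"``; see
    :func:`list_fixture_models`.  The fixtures encode the experimentally
    determined protonation/formation constants per temperature; hydrolysis
    constants and pKw values are flagged literature defaults (see each
    file's ``notes`` field).
    """
    from importlib.resources import files

    res = files("metallospec") / "data" / f"{name}.json"
    if not res.is_file():
        raise UsageError(
            f"no fixture model {name!r}; available: {list_fixture_models()}"
        )
    return _model_from_dict(json.loads(res.read_text()))


def list_fixture_models() -> list[str]:
    from importlib.resources import files

    data = files("metallospec") / "data"
    return sorted(p.name[:-5] for p in data.iterdir() if p.name.endswith(".json"))


def load_model(path: str | Path) -> EquilibriumModel:
    """Read an equilibrium model from its JSON interchange document."""
    with open(path) as fh:
        return _model_from_dict(json.load(fh))


def save_model(model: EquilibriumModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=2)
        fh.write("\n")
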