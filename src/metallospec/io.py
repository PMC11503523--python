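"""Readers and writers for the interchange formats.

Titration datasets travel as CSV with a typed key-value comment header
(``# key: value``, JSON-encoded values) followed by the observation
columns; distribution curves, thermo tables and RDF results are plain CSV.
Floats are written with ``repr`` so every numeric value round-trips
bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibrium import DistributionCurve
from .errors import UsageError
from .rdf import RdfResult
from .thermo import TemperatureSeries, ThermoResult
from .titration import PotentiometricCalibration, TitrationDataset, TitrationDesign

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_distribution",
    "write_rdf",
    "read_thermo_table",
    "thermo_result_to_dict",
]

_MAGIC = "# metallospec titration dataset v1"


def _fmt(v: float) -> str:
    return repr(float(v))


def _header_lines(ds: TitrationDataset) -> list[str]:
    head: dict = {"kind": ds.kind, "temperature_K": ds.temperature}
    if ds.design is not None:
        d = ds.design
        head.update(
            initial_volume_L=d.initial_volume,
            initial_composition=d.initial_composition,
            titrant=d.titrant,
            titrant_concentration_M=d.titrant_concentration,
        )
    if ds.calibration is not None:
        c = ds.calibration
        head.update(
            E0_mV=c.E0,
            nernst_mV=c.nernst,
            junction_acid=c.junction_acid,
            junction_base=c.junction_base,
        )
    if ds.totals is not None:
        head["totals"] = ds.totals
    if ds.kind == "absorbance":
        head["path_length_cm"] = ds.path_length
    if ds.metadata:
        head["metadata"] = ds.metadata
    return [_MAGIC] + [f"# {k}: {json.dumps(v)}" for k, v in head.items()]


def write_dataset(ds: TitrationDataset, path: str | Path) -> None:
    lines = _header_lines(ds)
    if ds.kind == "emf":
        lines.append("volume_L,emf_mV")
        for v, e in zip(ds.volumes, ds.emf):
            lines.append(f"{_fmt(v)},{_fmt(e)}")
    elif ds.kind == "absorbance":
        cols = ",".join(f"Abs@{_fmt(w)}" for w in ds.wavelengths)
        lines.append(f"pH,{cols}")
        for ph, row in zip(ds.pH, ds.absorbance):
            lines.append(_fmt(ph) + "," + ",".join(_fmt(a) for a in row))
    else:
        cols = ",".join(f"delta_ppm@{n}" for n in ds.nuclei)
        lines.append(f"pH,{cols}")
        for ph, row in zip(ds.pH, ds.shifts):
            lines.append(_fmt(ph) + "," + ",".join(_fmt(s) for s in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_dataset(path: str | Path) -> TitrationDataset:
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != _MAGIC:
        raise UsageError(f"{path} is not a metallospec titration dataset")
    head: dict = {}
    body_start = 1
    for i, line in enumerate(text[1:], start=1):
        if line.startswith("# "):
            key, _, raw = line[2:].partition(":")
            head[key.strip()] = json.loads(raw)
        else:
            body_start = i
            break
    df = pd.read_csv(Path(path), comment="#", float_precision="round_trip")
    kind = head["kind"]
    temperature = float(head["temperature_K"])
    design = None
    if "initial_volume_L" in head:
        design = TitrationDesign(
            initial_volume=head["initial_volume_L"],
            initial_composition=head["initial_composition"],
            titrant=head["titrant"],
            titrant_concentration=head["titrant_concentration_M"],
            additions=df["volume_L"].tolist() if "volume_L" in df else [],
            temperature=temperature,
        )
    calib = None
    if "E0_mV" in head:
        calib = PotentiometricCalibration(
            E0=head["E0_mV"],
            nernst=head["nernst_mV"],
            junction_acid=head["junction_acid"],
            junction_base=head["junction_base"],
        )
    ds = TitrationDataset(
        kind=kind,
        temperature=temperature,
        design=design,
        calibration=calib,
        totals=head.get("totals"),
        path_length=head.get("path_length_cm", 1.0),
        metadata=head.get("metadata", {}),
    )
    if kind == "emf":
        ds.volumes = df["volume_L"].to_numpy()
        ds.emf = df["emf_mV"].to_numpy()
    elif kind == "absorbance":
        ds.pH = df["pH"].to_numpy()
        wl_cols = [c for c in df.columns if c.startswith("Abs@")]
        ds.wavelengths = np.array([float(c[4:]) for c in wl_cols])
        ds.absorbance = df[wl_cols].to_numpy()
    else:
        ds.pH = df["pH"].to_numpy()
        cols = [c for c in df.columns if c.startswith("delta_ppm@")]
        ds.nuclei = [c[len("delta_ppm@"):] for c in cols]
        ds.shifts = df[cols].to_numpy()
    return ds


def write_distribution(curve: DistributionCurve, path_or_buf) -> None:
    """Distribution CSV: pH, per-species % columns, then mol/L columns."""
    pct_cols = [f"{lab}_percent" for lab in curve.labels]
    conc_labels = list(curve.concentrations)
    lines = ["pH," + ",".join(pct_cols) + "," + ",".join(f"{l}_M" for l in conc_labels)]
    for i, ph in enumerate(curve.pH):
        row = [_fmt(ph)]
        row += [_fmt(v) for v in curve.percent[i]]
        row += [_fmt(curve.concentrations[l][i]) for l in conc_labels]
        lines.append(",".join(row))
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        Path(path_or_buf).write_text(text)


def write_rdf(result: RdfResult, path: str | Path) -> None:
    lines = ["r_A,g,coordination_number"]
    for r, g, n in zip(result.r, result.g, result.coordination):
        lines.append(f"{_fmt(r)},{_fmt(g)},{_fmt(n)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_thermo_table(path: str | Path) -> dict[str, TemperatureSeries]:
    """Thermo CSV (reaction,T_K,log_beta[,SD]) into per-reaction series."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"reaction", "T_K", "log_beta"}
    if not required <= set(df.columns):
        raise UsageError(f"thermo table must have columns {sorted(required)}")
    out = {}
    for name, grp in df.groupby("reaction", sort=False):
        sd = None
        if "SD" in grp.columns and grp["SD"].notna().all():
            sd = grp["SD"].to_numpy(dtype=float)
        out[str(name)] = TemperatureSeries(
            temperatures=grp["T_K"].to_numpy(dtype=float),
            log_beta=grp["log_beta"].to_numpy(dtype=float),
            sd=sd,
        )
    return out


def thermo_result_to_dict(result: ThermoResult) -> dict:
    return {
        "delta_H_kJ_mol": result.delta_H,
        "delta_H_sd_kJ_mol": result.delta_H_sd,
        "log_beta_theta": result.log_beta_theta,
        "log_beta_theta_sd": result.log_beta_theta_sd,
        "delta_G_kJ_mol": result.delta_G,
        "T_delta_S_kJ_mol": result.T_delta_S,
        "theta_K": result.theta,
        "weighted": result.weighted,
    }
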