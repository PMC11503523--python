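"""Weighted nonlinear refinement of equilibrium constants and calibrations.

Potentiometric refinement minimises the weighted sum of squared emf
residuals over one or more titrations, sharing log beta between titrations
while giving each its own electrode parameters.  Weights propagate the two
instrument variances through the local curve slope,

    w_k = 1 / (sigma_E^2 + (dE/dv)_k^2 sigma_v^2),

so points on the steep equivalence jump, where a volume error masquerades
as a large emf error, are down-weighted.

Spectrophotometric and NMR refinement use a separable (variable projection)
structure: for each trial set of constants, speciation is solved and the
linear parameters (molar absorptivities per wavelength, or species shifts
per nucleus) are obtained by linear least squares; the outer loop iterates
only over the constants.

Parameter tokens
----------------
``"log_beta:LABEL"`` (shared), ``"E0:i"``, ``"slope:i"``,
``"junction_acid:i"``, ``"junction_base:i"``, ``"conc:i:COMPONENT"``, where
``i`` is a dataset index or ``*`` to expand over all datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.optimize import nnls as scipy_nnls

from .equilibrium import solve_state
from .errors import ConvergenceError, UsageError
from .model import EquilibriumModel
from .titration import (
    TitrationDataset,
    ligand_mole_fractions,
    simulate_potentiometric,
    _species_concentration_matrix,
    _chromophore_labels,
)

__all__ = [
    "WeightSpec",
    "RefinementSpec",
    "RefinementResult",
    "SelectionCriteria",
    "CandidateResult",
    "SelectionResult",
    "refine",
    "refine_spectra",
    "refine_shifts",
    "select_model",
    "max_formation_percent",
]


@dataclass
class WeightSpec:
    """Instrument standard deviations feeding the observation weights."""

    emf_sd: float = 0.15  # mV
    volume_sd: float = 0.002  # mL
    abs_sd: float = 0.002  # absorbance units
    shift_sd: float = 0.002  # ppm


@dataclass
class RefinementSpec:
    """What to refine and how hard to try."""

    free_parameters: list[str]
    weights: WeightSpec = field(default_factory=WeightSpec)
    max_iterations: int = 200
    tolerance: float = 1e-8  # convergence on the scaled parameter step
    ligand: str = "GMT"  # chromophore / observed nucleus carrier


@dataclass
class RefinementResult:
    """Refined values, their SDs, and fit statistics."""

    values: dict[str, float]
    sd: dict[str, float]
    residuals: np.ndarray  # weighted residual vector
    sigma_fit: float  # weighted RMS of residuals
    converged: bool
    n_evaluations: int
    n_observations: int
    n_parameters: int
    flagged_parameters: list[str] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# parameter bookkeeping


_PER_DATASET = ("E0", "slope", "junction_acid", "junction_base")


def _expand_tokens(tokens: Sequence[str], datasets, model) -> list[str]:
    out: list[str] = []
    labels = set(model.species_labels)
    for tok in tokens:
        parts = tok.split(":")
        head = parts[0]
        if head == "log_beta":
            if len(parts) != 2 or parts[1] not in labels:
                raise UsageError(f"unknown log_beta parameter {tok!r}")
            out.append(tok)
        elif head in _PER_DATASET:
            if len(parts) != 2:
                raise UsageError(f"malformed parameter {tok!r}")
            idxs = range(len(datasets)) if parts[1] == "*" else [int(parts[1])]
            for i in idxs:
                if not 0 <= i < len(datasets):
                    raise UsageError(f"dataset index out of range in {tok!r}")
                out.append(f"{head}:{i}")
        elif head == "conc":
            if len(parts) != 3:
                raise UsageError(f"malformed parameter {tok!r}")
            idxs = range(len(datasets)) if parts[1] == "*" else [int(parts[1])]
            for i in idxs:
                comp = parts[2]
                ds = datasets[i]
                comp_map = (
                    ds.design.initial_composition if ds.design is not None else ds.totals
                )
                if comp not in comp_map:
                    raise UsageError(f"component {comp!r} absent from dataset {i}")
                out.append(f"conc:{i}:{comp}")
        else:
            raise UsageError(f"unknown parameter token {tok!r}")
    if not out:
        raise UsageError("at least one free parameter is required")
    if len(set(out)) != len(out):
        raise UsageError("duplicate free parameters after expansion")
    return out


def _initial_values(tokens, datasets, model) -> np.ndarray:
    p0 = []
    for tok in tokens:
        parts = tok.split(":")
        if parts[0] == "log_beta":
            p0.append(model.get_species(parts[1]).log_beta)
        elif parts[0] == "E0":
            p0.append(datasets[int(parts[1])].calibration.E0)
        elif parts[0] == "slope":
            ds = datasets[int(parts[1])]
            p0.append(ds.calibration.slope_at(ds.temperature))
        elif parts[0] == "junction_acid":
            p0.append(datasets[int(parts[1])].calibration.junction_acid)
        elif parts[0] == "junction_base":
            p0.append(datasets[int(parts[1])].calibration.junction_base)
        elif parts[0] == "conc":
            i, comp = int(parts[1]), parts[2]
            ds = datasets[i]
            comp_map = ds.design.initial_composition if ds.design else ds.totals
            p0.append(comp_map[comp])
    return np.array(p0, dtype=float)


def _apply_parameters(tokens, p, datasets, model):
    """Return (updated model, per-dataset (design, calibration, totals))."""
    lb_updates = {}
    per_ds: dict[int, dict] = {}
    for tok, val in zip(tokens, p):
        parts = tok.split(":")
        if parts[0] == "log_beta":
            lb_updates[parts[1]] = val
        else:
            i = int(parts[1])
            per_ds.setdefault(i, {})[
                (parts[0], parts[2]) if parts[0] == "conc" else (parts[0], None)
            ] = val
    m = model.with_log_betas(lb_updates) if lb_updates else model
    updated = []
    for i, ds in enumerate(datasets):
        calib = ds.calibration
        design = ds.design
        totals = ds.totals
        mods = per_ds.get(i, {})
        if calib is not None and any(k[0] in _PER_DATASET for k in mods):
            calib = replace(
                calib,
                E0=mods.get(("E0", None), calib.E0),
                nernst=mods.get(
                    ("slope", None),
                    calib.nernst,
                ),
                junction_acid=mods.get(("junction_acid", None), calib.junction_acid),
                junction_base=mods.get(("junction_base", None), calib.junction_base),
            )
        conc_mods = {k[1]: v for k, v in mods.items() if k[0] == "conc"}
        if conc_mods:
            if design is not None:
                comp = dict(design.initial_composition)
                comp.update(conc_mods)
                design = replace(design, initial_composition=comp)
            else:
                totals = dict(totals)
                totals.update(conc_mods)
        updated.append((design, calib, totals))
    return m, updated


def _finish(tokens, res, n_obs, diagnostics, extras):
    p = res.x
    n_par = p.size
    dof = max(n_obs - n_par, 1)
    sigma_fit = float(np.sqrt(2.0 * res.cost / dof))
    J = res.jac
    flagged: list[str] = []
    sds = np.full(n_par, np.nan)
    try:
        U, s, Vt = np.linalg.svd(J, full_matrices=False)
        tiny = s < s[0] * 1e-10
        if np.any(tiny):
            for row in Vt[tiny]:
                flagged.append(tokens[int(np.argmax(np.abs(row)))])
            diagnostics.append(
                f"rank-deficient Jacobian; unidentifiable: {sorted(set(flagged))}"
            )
        s_inv = np.where(tiny, 0.0, 1.0 / np.maximum(s, 1e-300))
        cov = (Vt.T * s_inv**2) @ Vt * sigma_fit**2
        sds = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        diagnostics.append("covariance computation failed")
    converged = res.status > 0
    if not converged:
        diagnostics.append(f"optimizer did not converge: {res.message}")
    return RefinementResult(
        values=dict(zip(tokens, map(float, p))),
        sd=dict(zip(tokens, map(float, sds))),
        residuals=res.fun.copy(),
        sigma_fit=sigma_fit,
        converged=converged,
        n_evaluations=int(res.nfev),
        n_observations=int(n_obs),
        n_parameters=int(n_par),
        flagged_parameters=sorted(set(flagged)),
        diagnostics=diagnostics,
        extras=extras,
    )


def _check_problem_size(n_obs, n_par):
    if n_obs < n_par + 5:
        raise UsageError(
            f"{n_obs} observations cannot constrain {n_par} parameters "
            "(need at least free parameters + 5)"
        )


def _run_lm(fun, p0, spec, n_obs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return least_squares(
            fun,
            p0,
            method="lm",
            diff_step=1e-4,
            xtol=spec.tolerance,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=spec.max_iterations * (p0.size + 1),
        )


# ---------------------------------------------------------------------------
# potentiometric refinement


def _emf_weights(ds: TitrationDataset, w: WeightSpec) -> np.ndarray:
    v_ml = np.asarray(ds.volumes, dtype=float) * 1000.0
    slope = np.gradient(np.asarray(ds.emf, dtype=float), v_ml)
    var = w.emf_sd**2 + slope**2 * w.volume_sd**2
    return 1.0 / var


def refine(
    datasets: Sequence[TitrationDataset],
    model: EquilibriumModel,
    spec: RefinementSpec,
) -> RefinementResult:
    """Refine constants/calibrations against potentiometric datasets."""
    if not datasets:
        raise UsageError("no datasets supplied")
    for ds in datasets:
        if ds.kind != "emf":
            raise UsageError("refine() expects 'emf' datasets; see refine_spectra/_shifts")
        if abs(ds.temperature - model.temperature) > 1e-9:
            raise UsageError("dataset and model temperatures differ")
    tokens = _expand_tokens(spec.free_parameters, datasets, model)
    p0 = _initial_values(tokens, datasets, model)
    n_obs = int(sum(len(ds.emf) for ds in datasets))
    _check_problem_size(n_obs, p0.size)
    sqrt_w = [np.sqrt(_emf_weights(ds, spec.weights)) for ds in datasets]
    diagnostics: list[str] = []

    def residuals(p):
        m, per_ds = _apply_parameters(tokens, p, datasets, model)
        out = []
        for i, ds in enumerate(datasets):
            design, calib, _ = per_ds[i]
            try:
                _, emf = simulate_potentiometric(
                    design, m, calib, volumes=ds.volumes
                )
            except ConvergenceError:
                out.append(np.full(len(ds.emf), 1e6))
                continue
            out.append((np.asarray(ds.emf) - emf) * sqrt_w[i])
        return np.concatenate(out)

    res = _run_lm(residuals, p0, spec, n_obs)
    return _finish(tokens, res, n_obs, diagnostics, extras={})


# ---------------------------------------------------------------------------
# separable refinements (spectra, shifts)


def _separable_refine(datasets, model, spec, kind):
    if not datasets:
        raise UsageError("no datasets supplied")
    for ds in datasets:
        if ds.kind != kind:
            raise UsageError(f"expected {kind!r} datasets")
        if abs(ds.temperature - model.temperature) > 1e-9:
            raise UsageError("dataset and model temperatures differ")
    if kind == "absorbance":
        axis0 = datasets[0].wavelengths
        same = all(np.array_equal(ds.wavelengths, axis0) for ds in datasets)
        obs_key, sd = "absorbance", spec.weights.abs_sd
    else:
        axis0 = datasets[0].nuclei
        same = all(ds.nuclei == axis0 for ds in datasets)
        obs_key, sd = "shifts", spec.weights.shift_sd
    if not same:
        raise UsageError("datasets must share the same wavelength/nucleus grid")

    tokens = _expand_tokens(spec.free_parameters, datasets, model)
    bad = [t for t in tokens if not (t.startswith("log_beta") or t.startswith("conc"))]
    if bad:
        raise UsageError(f"separable refinement only frees log_beta/conc: {bad}")
    p0 = _initial_values(tokens, datasets, model)
    labels = _chromophore_labels(model, spec.ligand)
    n_obs = int(sum(getattr(ds, obs_key).size for ds in datasets))
    _check_problem_size(n_obs, p0.size + len(labels) * len(axis0))
    diagnostics: list[str] = []
    clip_note = {"clipped": False}

    def design_matrix(m, per_ds):
        blocks = []
        for i, ds in enumerate(datasets):
            _, _, totals = per_ds[i]
            if kind == "absorbance":
                C = _species_concentration_matrix(ds.pH, m, totals, labels)
                mult = np.array(
                    [
                        m.get_species(lab).coefficient(spec.ligand)
                        if lab != spec.ligand
                        else 1.0
                        for lab in labels
                    ]
                )
                blocks.append(ds.path_length * C * mult)
            else:
                _, X = ligand_mole_fractions(ds.pH, m, totals, spec.ligand)
                blocks.append(X)
        return np.vstack(blocks)

    Y = np.vstack([np.asarray(getattr(ds, obs_key), dtype=float) for ds in datasets])

    def solve_linear(A):
        coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
        return coef

    def residuals(p):
        m, per_ds = _apply_parameters(tokens, p, datasets, model)
        try:
            A = design_matrix(m, per_ds)
        except ConvergenceError:
            return np.full(n_obs, 1e6)
        coef = solve_linear(A)
        return ((Y - A @ coef) / sd).ravel()

    res = _run_lm(residuals, p0, spec, n_obs)
    # recompute the linear solution at the optimum for reporting; negative
    # absorptivities (noise at band tails) are clipped only here, so the
    # outer beta fit stays an unbiased unconstrained least squares
    m, per_ds = _apply_parameters(tokens, res.x, datasets, model)
    A = design_matrix(m, per_ds)
    coef = solve_linear(A)
    if kind == "absorbance" and np.any(coef < 0):
        warnings.warn(
            "negative molar absorptivities clipped to zero in the report",
            RuntimeWarning,
        )
        diagnostics.append(
            f"{int(np.sum(coef < 0))} negative epsilon values clipped to zero"
        )
        coef = np.clip(coef, 0.0, None)
    if kind == "absorbance":
        extras = {
            "epsilon": {lab: coef[j].copy() for j, lab in enumerate(labels)},
            "wavelengths": np.asarray(axis0, dtype=float).copy(),
        }
    else:
        extras = {
            "delta": {
                lab: dict(zip(axis0, map(float, coef[j]))) for j, lab in enumerate(labels)
            },
            "nuclei": list(axis0),
        }
    return _finish(tokens, res, n_obs, diagnostics, extras)


def refine_spectra(datasets, model, spec: RefinementSpec) -> RefinementResult:
    """Refine constants with molar absorptivities as linear parameters.

    The per-wavelength epsilon profiles of every chromophore environment are
    reported in ``result.extras["epsilon"]``; negative unconstrained
    solutions are clipped to zero with a warning.
    """
    return _separable_refine(datasets, model, spec, "absorbance")


def refine_shifts(datasets, model, spec: RefinementSpec) -> RefinementResult:
    """Refine constants with species chemical shifts as linear parameters."""
    return _separable_refine(datasets, model, spec, "shift")


# ---------------------------------------------------------------------------
# model selection


@dataclass
class SelectionCriteria:
    """Ranking rules for candidate speciation models.

    A larger model displaces a smaller one only if it reduces sigma_fit by
    more than ``sigma_improvement`` (fractional); any candidate containing a
    species whose maximum formation percentage over ``pH_window`` stays
    below ``percent_floor`` is rejected.  ``fixed_labels`` lists species
    whose constants are held (protonation, hydrolysis); the remaining
    candidate species are refined, along with any ``extra_free`` tokens.
    """

    sigma_improvement: float = 0.2
    percent_floor: float = 5.0
    pH_window: tuple[float, float] = (2.0, 10.0)
    fixed_labels: tuple[str, ...] = ()
    extra_free: tuple[str, ...] = ()
    weights: WeightSpec = field(default_factory=WeightSpec)
    max_iterations: int = 200
    ligand: str = "GMT"


@dataclass
class CandidateResult:
    labels: tuple[str, ...]
    result: RefinementResult | None
    sigma_fit: float
    max_percent: dict[str, float]
    rejected: list[str]
    model: EquilibriumModel | None


@dataclass
class SelectionResult:
    ranked: list[CandidateResult]
    chosen: CandidateResult


def max_formation_percent(
    model: EquilibriumModel,
    totals,
    labels: Sequence[str],
    window: tuple[float, float] = (2.0, 10.0),
    step: float = 0.2,
) -> dict[str, float]:
    """Maximum formation percentage of each species over a pH window.

    The percentage is relative to the species' natural reference: the
    ligand-like component it contains if any (any non-H component shared
    with the other species), else the metal; concretely, the non-H component
    with the smallest total among those in its stoichiometry (the limiting
    reagent convention).
    """
    grid = np.arange(window[0], window[1] + 1e-9, step)
    out = {lab: 0.0 for lab in labels}
    warm = None
    names = model.component_names
    for ph in grid:
        st = solve_state(model, totals, fixed_pH=ph, initial_free=warm)
        warm = {nm: st.free_concentrations[nm] for nm in names if nm != "H"}
        for lab in labels:
            sp = model.get_species(lab)
            refs = [c for c in sp.stoichiometry if c != "H" and sp.coefficient(c) != 0]
            if not refs:
                continue
            ref = min(refs, key=lambda c: totals[c])
            pct = (
                100.0
                * abs(sp.coefficient(ref))
                * st.species_concentrations[lab]
                / totals[ref]
            )
            out[lab] = max(out[lab], pct)
    return out


def select_model(
    datasets: Sequence[TitrationDataset],
    model: EquilibriumModel,
    candidates: Sequence[Sequence[str]],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> SelectionResult:
    """Refine each candidate species set and pick the best model.

    Ranking is lexicographic: a candidate with more species must beat the
    simpler one's sigma_fit by the configured margin; candidates carrying a
    species that never forms appreciably (below the percentage floor over
    the pH window) are rejected outright.
    """
    if not candidates:
        raise UsageError("no candidate models supplied")
    results: list[CandidateResult] = []
    failures = []
    for cand in candidates:
        labels = tuple(cand)
        sub = model.subset(labels)
        free = [
            f"log_beta:{lab}" for lab in labels if lab not in criteria.fixed_labels
        ]
        spec = RefinementSpec(
            free_parameters=free + list(criteria.extra_free),
            weights=criteria.weights,
            max_iterations=criteria.max_iterations,
            ligand=criteria.ligand,
        )
        try:
            if datasets[0].kind == "emf":
                res = refine(datasets, sub, spec)
            elif datasets[0].kind == "absorbance":
                res = refine_spectra(datasets, sub, spec)
            else:
                res = refine_shifts(datasets, sub, spec)
        except (ConvergenceError, UsageError) as exc:
            failures.append(f"{labels}: {exc}")
            results.append(
                CandidateResult(labels, None, np.inf, {}, [f"refinement failed: {exc}"], None)
            )
            continue
        refined = sub.with_log_betas(
            {
                tok.split(":", 1)[1]: val
                for tok, val in res.values.items()
                if tok.startswith("log_beta:")
            }
        )
        rejected = list(res.flagged_parameters)
        if not res.converged:
            rejected.append("refinement did not converge")
        check_labels = [lab for lab in labels if lab not in criteria.fixed_labels]
        pct: dict[str, float] = {}
        for ds in datasets:
            totals = (
                ds.design.initial_composition if ds.design is not None else ds.totals
            )
            this = max_formation_percent(
                refined, totals, check_labels, criteria.pH_window
            )
            for lab, v in this.items():
                pct[lab] = max(pct.get(lab, 0.0), v)
        for lab, v in pct.items():
            if v < criteria.percent_floor:
                rejected.append(
                    f"species {lab!r} peaks at {v:.2f}% (< {criteria.percent_floor}% floor)"
                )
        results.append(
            CandidateResult(labels, res, res.sigma_fit, pct, rejected, refined)
        )
    if all(r.result is None for r in results):
        raise ConvergenceError(
            "no candidate model converged: " + "; ".join(failures)
        )
    qualified = [r for r in results if r.result is not None and not r.rejected]
    pool = qualified if qualified else [r for r in results if r.result is not None]
    pool = sorted(pool, key=lambda r: (len(r.labels), r.sigma_fit))
    chosen = pool[0]
    for cand in pool[1:]:
        if cand.sigma_fit < chosen.sigma_fit * (1.0 - criteria.sigma_improvement):
            chosen = cand
    ranked = sorted(
        results,
        key=lambda r: (r is not chosen, bool(r.rejected), r.sigma_fit),
    )
    return SelectionResult(ranked=ranked, chosen=chosen)
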