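"""Mass-balance speciation solving.

Given analytical (total) concentrations of every component, the solver finds
the free concentrations satisfying, for each component j,

    T_j = [X_j] + sum_s  nu_sj * beta_s * prod_k [X_k]^nu_sk

with the proton balance additionally carrying the hydroxide term -Kw/[H]
(hydroxide is not a component; see :mod:`metallospec.model`).  The proton
total is the *analytical* one — mineral acid minus strong base — and may be
negative in alkaline solution.

Unknowns are iterated in log-space (guaranteeing positivity) with a damped
Newton method using the analytic Jacobian; steps are halved whenever the
scaled residual norm would increase.  This is robust across the constant
spreads met here (beta from 1e-13 to 1e8 within one model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConvergenceError, ModelError, UsageError
from .model import EquilibriumModel

__all__ = ["SolutionState", "DistributionCurve", "solve_state", "distribution_curve"]

_LN10 = np.log(10.0)


@dataclass
class SolutionState:
    """Free and species concentrations (mol/L) at one solved point."""

    free_concentrations: dict[str, float]
    species_concentrations: dict[str, float]
    pH: float


@dataclass
class DistributionCurve:
    """Formation percentages of reference-containing species along a pH grid.

    ``labels`` lists every species containing the reference component plus
    the free reference itself (under the component's own name); ``percent``
    holds 100 * nu_ref * c / T_ref so the columns sum to 100 at every grid
    point by mass balance.  ``concentrations`` additionally stores every
    species (and free component) in mol/L.
    """

    pH: np.ndarray
    reference: str
    labels: list[str]
    percent: np.ndarray  # (n_pH, n_labels)
    concentrations: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# Newton core


def _residual_jacobian(lnx, N, lnbeta, kw, h_idx, totals):
    """Scaled mass-balance residual, Jacobian (d/d ln x) and species conc."""
    x = np.exp(lnx)
    c = np.exp(lnbeta + N @ lnx) if N.shape[0] else np.zeros(0)
    calc = x + (N.T @ c if N.shape[0] else 0.0)
    gross = x + (np.abs(N).T @ c if N.shape[0] else 0.0)
    if h_idx is not None:
        oh = kw / x[h_idx]
        calc = calc.copy()
        gross = gross.copy()
        calc[h_idx] -= oh
        gross[h_idx] += oh
    r = calc - totals
    scale = np.maximum(np.maximum(np.abs(totals), gross), 1e-300)
    n = len(lnx)
    J = np.diag(x).astype(float)
    if N.shape[0]:
        J += N.T @ (c[:, None] * N)
    if h_idx is not None:
        J[h_idx, h_idx] += kw / x[h_idx]
    return r, scale, J, x, c


def _newton(N, lnbeta, kw, h_idx, totals, lnx0, tol, max_iter):
    lnx = lnx0.copy()
    r, scale, J, x, c = _residual_jacobian(lnx, N, lnbeta, kw, h_idx, totals)
    phi = np.max(np.abs(r / scale))
    for it in range(max_iter):
        if phi <= tol:
            return lnx, x, c, True, r / scale, it
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -r, rcond=None)[0]
        # cap at ~3 decades per component per iteration
        m = np.max(np.abs(step))
        if m > 7.0:
            step *= 7.0 / m
        lam = 1.0
        accepted = False
        for _ in range(40):
            trial = lnx + lam * step
            r_t, scale_t, J_t, x_t, c_t = _residual_jacobian(
                trial, N, lnbeta, kw, h_idx, totals
            )
            phi_t = np.max(np.abs(r_t / scale_t))
            if phi_t < phi:
                lnx, r, scale, J, x, c, phi = trial, r_t, scale_t, J_t, x_t, c_t, phi_t
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            # take the tiny step anyway; helps crawl out of flat regions
            lnx = lnx + lam * step
            r, scale, J, x, c = _residual_jacobian(lnx, N, lnbeta, kw, h_idx, totals)
            phi = np.max(np.abs(r / scale))
    return lnx, x, c, phi <= tol, r / scale, max_iter


def _initial_guesses(totals, names, h_idx, kw):
    """Candidate starting points (ln free concentrations)."""
    base = np.empty(len(names))
    for i, nm in enumerate(names):
        if i == h_idx:
            continue
        base[i] = np.log(max(totals[i], 1e-30) * 0.5)
    guesses = []
    if h_idx is None:
        guesses.append(base.copy())
        g = base.copy() - _LN10  # one decade lower
        guesses.append(g)
        return guesses
    th = totals[h_idx]
    h_starts = [np.sqrt(kw)]
    if th > 0:
        h_starts.insert(0, th)
    else:
        h_starts.insert(0, kw / max(-th, np.sqrt(kw)))
    h_starts += [1e-3, 1e-7, 1e-11]
    for h0 in h_starts:
        g = base.copy()
        g[h_idx] = np.log(h0)
        guesses.append(g)
    return guesses


def solve_state(
    model: EquilibriumModel,
    totals: Mapping[str, float],
    fixed_pH: float | None = None,
    *,
    tol: float = 1e-12,
    max_iter: int = 200,
    initial_free: Mapping[str, float] | None = None,
) -> SolutionState:
    """Solve the mass balances of ``model`` at given analytical totals.

    Parameters
    ----------
    model
        Equilibrium model (components, species, pKw).
    totals
        Analytical concentration per component, mol/L.  Strictly positive
        for every non-H component.  If ``fixed_pH`` is None, ``totals["H"]``
        must hold the analytical proton total (mineral acid corrected; may
        be negative).
    fixed_pH
        If given, [H+] is clamped at ``10**-fixed_pH`` and H is removed from
        the unknowns (its balance is absorbed by the titrant/electrode).
    tol
        Convergence threshold on the scaled mass-balance residual.
    initial_free
        Optional warm start: free concentrations from a neighbouring point.

    Returns
    -------
    SolutionState
        Free and species concentrations; hydroxide is reported under the
        ``"OH"`` key of ``species_concentrations``.

    Raises
    ------
    ConvergenceError
        If no starting point converges within ``max_iter`` iterations.
    ModelError
        If the model admits no positive solution (e.g. a required total is
        missing or non-positive).
    """
    names = model.component_names
    h_pos = names.index("H")
    kw = 10.0 ** (-model.pKw)

    for nm in names:
        if nm == "H":
            continue
        if nm not in totals:
            raise ModelError(f"missing total concentration for component {nm!r}")
        if not totals[nm] > 0:
            raise ModelError(f"total for component {nm!r} must be strictly positive")
    if fixed_pH is None and "H" not in totals:
        raise ModelError("totals must include the analytical H total when pH is free")

    N_full = model.stoichiometry_matrix()
    lnbeta_full = model.log_betas() * _LN10

    if fixed_pH is not None:
        h_free = 10.0 ** (-float(fixed_pH))
        keep = [i for i in range(len(names)) if i != h_pos]
        if not keep:  # only H declared: nothing to solve
            return _pack_state(model, np.array([h_free]), None, kw)
        # fold the fixed [H] into the effective betas
        lnbeta = lnbeta_full + N_full[:, h_pos] * np.log(h_free)
        N = N_full[:, keep]
        tvec = np.array([totals[names[i]] for i in keep])
        h_idx = None
        sub_names = [names[i] for i in keep]
    else:
        N = N_full
        tvec = np.array([float(totals[nm]) for nm in names])
        lnbeta = lnbeta_full
        h_idx = h_pos
        sub_names = names

    guesses = _initial_guesses(tvec, sub_names, h_idx, kw)
    if initial_free is not None:
        warm = np.array(
            [np.log(initial_free[nm]) for nm in sub_names]
        )
        guesses.insert(0, warm)

    last_scaled = None
    for lnx0 in guesses:
        lnx, x, c, ok, scaled_r, _ = _newton(N, lnbeta, kw, h_idx, tvec, lnx0, tol, max_iter)
        if ok:
            full_x = np.empty(len(names))
            if fixed_pH is not None:
                for j, i in enumerate([i for i in range(len(names)) if i != h_pos]):
                    full_x[i] = x[j]
                full_x[h_pos] = h_free
            else:
                full_x = x
            return _pack_state(model, full_x, c, kw)
        last_scaled = scaled_r
    raise ConvergenceError(
        "equilibrium solver did not converge",
        residuals=last_scaled,
        iterations=max_iter,
    )


def _pack_state(model, free_vec, c, kw):
    names = model.component_names
    free = {nm: float(v) for nm, v in zip(names, free_vec)}
    h = free["H"]
    # species concentrations from mass action on the final free values
    N = model.stoichiometry_matrix()
    lnx = np.log(free_vec)
    conc = (
        np.exp(model.log_betas() * _LN10 + N @ lnx) if len(model.species) else np.zeros(0)
    )
    species = {sp.label: float(cv) for sp, cv in zip(model.species, conc)}
    species["OH"] = kw / h
    return SolutionState(
        free_concentrations=free,
        species_concentrations=species,
        pH=float(-np.log10(h)),
    )


def distribution_curve(
    model: EquilibriumModel,
    totals: Mapping[str, float],
    pH_grid: Sequence[float],
    reference_component: str,
    *,
    tol: float = 1e-12,
) -> DistributionCurve:
    """Species distribution versus pH at fixed analytical totals.

    For each grid point the mass balances are solved at clamped pH and each
    species containing ``reference_component`` is expressed as a percentage
    of that component's total; the free component itself appears as one of
    the curves, so the percentages sum to exactly 100.
    """
    grid = np.asarray(pH_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise UsageError("pH grid must be a non-empty 1-D sequence")
    if np.any(np.diff(grid) <= 0):
        raise UsageError("pH grid must be strictly increasing")
    if grid[0] < 0 or grid[-1] > 14:
        raise UsageError("pH grid must lie within [0, 14]")
    names = model.component_names
    if reference_component not in names:
        raise UsageError(f"reference component {reference_component!r} not in model")
    t_ref = float(totals[reference_component])

    ref_species = [
        sp for sp in model.species if sp.coefficient(reference_component) != 0
    ]
    labels = [sp.label for sp in ref_species] + [reference_component]

    n = grid.size
    percent = np.zeros((n, len(labels)))
    conc: dict[str, np.ndarray] = {
        lab: np.zeros(n) for lab in model.species_labels
    }
    conc["OH"] = np.zeros(n)
    for nm in names:
        conc[nm] = np.zeros(n)

    warm = None
    for i, ph in enumerate(grid):
        st = solve_state(model, totals, fixed_pH=ph, tol=tol, initial_free=warm)
        warm = {
            nm: st.free_concentrations[nm] for nm in names if nm != "H"
        }
        for nm in names:
            conc[nm][i] = st.free_concentrations[nm]
        for lab in model.species_labels:
            conc[lab][i] = st.species_concentrations[lab]
        conc["OH"][i] = st.species_concentrations["OH"]
        for j, sp in enumerate(ref_species):
            percent[i, j] = (
                100.0
                * sp.coefficient(reference_component)
                * st.species_concentrations[sp.label]
                / t_ref
            )
        percent[i, -1] = 100.0 * st.free_concentrations[reference_component] / t_ref
    return DistributionCurve(
        pH=grid, reference=reference_component, labels=labels,
        percent=percent, concentrations=conc,
    )
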