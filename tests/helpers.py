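"""Independent oracles used by the test suite.

These deliberately avoid the package's Newton solver and least-squares
machinery: brute-force grid scans, bisection and closed-form formulas, so
agreement is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np


def grid_search_speciation(model, totals, fixed_pH, comps, levels=14, n=41, span=9.0):
    """Brute-force 2-D logarithmic grid scan for the free concentrations.

    Scans log10 free concentrations of the two components in ``comps`` at
    clamped pH, scoring each grid point by the worst relative mass-balance
    error, and successively shrinks the grid around the best point.
    """
    h = 10.0 ** (-fixed_pH)
    species = [
        (10.0**sp.log_beta * h ** sp.coefficient("H"),
         sp.coefficient(comps[0]), sp.coefficient(comps[1]))
        for sp in model.species
    ]
    lo = np.array([np.log10(totals[c]) - span for c in comps])
    hi = np.array([np.log10(totals[c]) + 0.05 for c in comps])
    best = None
    for _ in range(levels):
        ga = np.logspace(lo[0], hi[0], n)
        gb = np.logspace(lo[1], hi[1], n)
        FA, FB = np.meshgrid(ga, gb, indexing="ij")
        ta = FA.copy()
        tb = FB.copy()
        for beta_eff, na, nb in species:
            c = beta_eff * FA**na * FB**nb
            ta += na * c
            tb += nb * c
        err = np.maximum(
            np.abs(ta - totals[comps[0]]) / totals[comps[0]],
            np.abs(tb - totals[comps[1]]) / totals[comps[1]],
        )
        i, j = np.unravel_index(np.argmin(err), err.shape)
        best = (ga[i], gb[j])
        da = (hi[0] - lo[0]) / (n - 1)
        db = (hi[1] - lo[1]) / (n - 1)
        lo = np.array([np.log10(best[0]) - 1.5 * da, np.log10(best[1]) - 1.5 * db])
        hi = np.array([np.log10(best[0]) + 1.5 * da, np.log10(best[1]) + 1.5 * db])
    return {comps[0]: best[0], comps[1]: best[1]}


def bisect_free_ligand(model, total_ligand, fixed_pH, ligand="GMT", iters=200):
    """1-D bisection on the free-ligand concentration at clamped pH."""
    h = 10.0 ** (-fixed_pH)
    species = [
        (10.0**sp.log_beta * h ** sp.coefficient("H"), sp.coefficient(ligand))
        for sp in model.species
        if sp.coefficient(ligand) != 0
    ]

    def calc_total(free):
        return free + sum(b * n * free**n for b, n in species)

    lo, hi = total_ligand * 1e-15, total_ligand
    for _ in range(iters):
        mid = np.sqrt(lo * hi)  # bisect in log space
        if calc_total(mid) < total_ligand:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def bisect_proton_acid_base(model, totals, ligand="GMT", iters=300):
    """Free [H+] for a single-protonation acid-base system by bisection.

    Given [H], the free ligand follows in closed form; the proton balance
    T_H = [H] - Kw/[H] + beta [H] [L] is monotone in [H].
    """
    beta = 10.0 ** model.get_species(f"({ligand})H").log_beta
    kw = 10.0 ** (-model.pKw)
    t_l = totals[ligand]
    t_h = totals["H"]

    def residual(h):
        free_l = t_l / (1.0 + beta * h)
        return h - kw / h + beta * h * free_l - t_h

    lo, hi = 1e-14, 1.0
    for _ in range(iters):
        mid = np.sqrt(lo * hi)
        if residual(mid) < 0:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def vant_hoff_slope_closed_form(temperatures, log_beta, theta=298.15):
    """Unweighted least-squares (intercept, slope) of log beta on 1/theta - 1/T."""
    x = 1.0 / theta - 1.0 / np.asarray(temperatures, dtype=float)
    y = np.asarray(log_beta, dtype=float)
    xm, ym = x.mean(), y.mean()
    slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    return ym - slope * xm, slope


def joint_spectra_least_squares(pH, absorbance, path_length, conc_of_beta, beta_grid):
    """Grid scan over log beta with full joint linear solve per trial.

    ``conc_of_beta(logb)`` must return the (n_pH, n_species) concentration
    matrix.  Returns the grid point minimising the full residual norm and
    the corresponding epsilon matrix.
    """
    best = None
    for logb in beta_grid:
        C = path_length * conc_of_beta(logb)
        eps, *_ = np.linalg.lstsq(C, absorbance, rcond=None)
        rss = float(np.sum((absorbance - C @ eps) ** 2))
        if best is None or rss < best[0]:
            best = (rss, logb, eps)
    return best[1], best[2]
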