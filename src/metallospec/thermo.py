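"""Temperature dependence of formation constants and derived thermodynamics.

The van't Hoff model with temperature-independent reaction enthalpy reads

    log beta(T) = log beta_theta - (dH / (R ln10)) * (1/T - 1/theta)

with theta = 298.15 K, from which

    dG(theta) = -R theta ln10 log beta_theta,     T dS = dH - dG.

Stepwise (partial) constants follow by differencing overall constants, e.g.
M + HL <=> MLH has log K = log beta(MLH) - log beta(HL), and the hydroxo
route MOH + L <=> MLOH has log K = log beta(MLOH) - log beta(MOH).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError

__all__ = [
    "R_GAS",
    "THETA",
    "TemperatureSeries",
    "ThermoResult",
    "stepwise_logK",
    "vant_hoff_fit",
    "gibbs_from_logK",
    "log_beta_at",
]

R_GAS = 8.314  # J K-1 mol-1
THETA = 298.15  # K
_LN10 = np.log(10.0)


@dataclass
class TemperatureSeries:
    """log beta of one reaction at several temperatures (K), optional SDs."""

    temperatures: np.ndarray
    log_beta: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.log_beta = np.asarray(self.log_beta, dtype=float)
        if self.temperatures.shape != self.log_beta.shape:
            raise UsageError("temperatures and log_beta must have equal length")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.log_beta.shape:
                raise UsageError("sd length mismatch")
            if np.any(self.sd <= 0):
                raise UsageError("SDs must be positive")
        if len(np.unique(self.temperatures)) < 2:
            raise UsageError("need at least two distinct temperatures")


@dataclass
class ThermoResult:
    """van't Hoff fit output at the reference temperature theta = 298.15 K.

    All energies in kJ/mol.
    """

    delta_H: float
    delta_H_sd: float
    log_beta_theta: float
    log_beta_theta_sd: float
    delta_G: float
    T_delta_S: float
    theta: float = THETA
    weighted: bool = False


def stepwise_logK(
    overall: float,
    reference: float,
    *,
    temperature: float | None = None,
    reference_temperature: float | None = None,
) -> float:
    """Partial formation constant by differencing overall constants.

    For MLH the reference is the ligand protonation constant (M + HL route);
    for MLOH it is the metal hydrolysis constant (MOH + L route).  When both
    temperatures are supplied they must agree.
    """
    if (
        temperature is not None
        and reference_temperature is not None
        and abs(temperature - reference_temperature) > 1e-9
    ):
        raise UsageError(
            f"temperature mismatch: {temperature} K vs {reference_temperature} K"
        )
    return float(overall) - float(reference)


def gibbs_from_logK(logK: float, T: float) -> float:
    """Standard free energy -RT ln10 logK, in kJ/mol."""
    if not T > 0:
        raise UsageError("temperature must be positive kelvin")
    return -R_GAS * T * _LN10 * float(logK) / 1000.0


def vant_hoff_fit(
    series: TemperatureSeries,
    *,
    weighted: bool | None = None,
    theta: float = THETA,
) -> ThermoResult:
    """Two-parameter van't Hoff fit of log beta versus temperature.

    Linear least squares of log beta on x = (1/theta - 1/T): the intercept
    is log beta at theta and the slope is dH/(R ln10).  Points are weighted
    by 1/SD^2 when SDs are present (default), or left unweighted.

    Parameter SDs come from the covariance of the linear problem scaled by
    the reduced chi-square when there are spare degrees of freedom.
    """
    T = series.temperatures
    y = series.log_beta
    if weighted is None:
        weighted = series.sd is not None
    if weighted and series.sd is None:
        raise UsageError("weighted fit requested but the series has no SDs")
    x = 1.0 / theta - 1.0 / T
    w = 1.0 / series.sd**2 if weighted else np.ones_like(y)

    X = np.column_stack([np.ones_like(x), x])
    XtW = X.T * w
    A = XtW @ X
    b = XtW @ y
    try:
        coef = np.linalg.solve(A, b)
        cov_unit = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise UsageError("degenerate temperature series") from exc
    resid = y - X @ coef
    dof = y.size - 2
    chi2 = float(np.sum(w * resid**2))
    scale = chi2 / dof if dof > 0 else 1.0
    cov = cov_unit * scale
    intercept, slope = coef
    sd_int, sd_slope = np.sqrt(np.diag(cov))

    dH = slope * R_GAS * _LN10 / 1000.0  # kJ/mol
    dH_sd = sd_slope * R_GAS * _LN10 / 1000.0
    dG = gibbs_from_logK(intercept, theta)
    return ThermoResult(
        delta_H=float(dH),
        delta_H_sd=float(dH_sd),
        log_beta_theta=float(intercept),
        log_beta_theta_sd=float(sd_int),
        delta_G=float(dG),
        T_delta_S=float(dH - dG),
        theta=theta,
        weighted=bool(weighted),
    )


def log_beta_at(result: ThermoResult, T: float) -> float:
    """Predict log beta at temperature T (K) from a fitted ThermoResult."""
    if not T > 0:
        raise UsageError("temperature must be positive kelvin")
    slope = result.delta_H * 1000.0 / (R_GAS * _LN10)
    return result.log_beta_theta + slope * (1.0 / result.theta - 1.0 / T)
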