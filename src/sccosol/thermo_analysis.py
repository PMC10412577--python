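"""Derived thermodynamics: enthalpies from correlation slopes, crossover
pressure, and the Mendez-Santiago-Teja self-consistency diagnostic.

The Chrastil temperature coefficient a1 equals dH_total/R (total = vaporization
+ solvation heat) and Bartle's a1 equals dH_vap/R; both are negative for
endothermic dissolution, so the reported enthalpy is -R*a1. Their difference
is the solvation enthalpy, conventionally quoted as a negative (exothermic)
value alongside its magnitude.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .core_data import R_GAS, SolubilityDataset, SoluteProperties
from .density_models import FittedModel, predict_mole_fraction


@dataclass(frozen=True)
class EnthalpyReport:
    dH_total: float  # kJ/mol, Chrastil route
    dH_vap: float  # kJ/mol, Bartle route
    dH_sol: float  # kJ/mol, signed difference

    def __post_init__(self) -> None:
        if not math.isclose(self.dH_sol, self.dH_total - self.dH_vap, rel_tol=0, abs_tol=1e-12):
            raise ValueError("dH_sol must equal dH_total - dH_vap exactly")

    @property
    def dH_sol_magnitude(self) -> float:
        return abs(self.dH_sol)


def _temperature_coefficient(source: FittedModel | float) -> float:
    if isinstance(source, FittedModel):
        # both Chrastil and Bartle carry the 1/T coefficient in slot 1
        return source.params[1]
    return float(source)


def total_enthalpy_from_chrastil(a1: FittedModel | float) -> float:
    """dH_total (kJ/mol) = -R * a1 from the Chrastil 1/T coefficient."""
    return -R_GAS * _temperature_coefficient(a1) / 1000.0


def vaporization_enthalpy_from_bartle(a1: FittedModel | float) -> float:
    """dH_vap (kJ/mol) = -R * a1 from the Bartle 1/T coefficient."""
    value = -R_GAS * _temperature_coefficient(a1) / 1000.0
    if value < 0:
        warnings.warn(
            "negative vaporization enthalpy implies exothermic sublimation - implausible",
            stacklevel=2,
        )
    return value


def solvation_enthalpy(dH_total: float, dH_vap: float) -> tuple[float, float]:
    """Signed solvation enthalpy and its magnitude (kJ/mol)."""
    signed = dH_total - dH_vap
    return signed, abs(signed)


def enthalpy_report(chrastil: FittedModel | float, bartle: FittedModel | float) -> EnthalpyReport:
    total = total_enthalpy_from_chrastil(chrastil)
    vap = vaporization_enthalpy_from_bartle(bartle)
    return EnthalpyReport(dH_total=total, dH_vap=vap, dH_sol=total - vap)


def crossover_pressure(
    isotherm_models: Mapping[float, FittedModel],
    density_fn: Callable[[float, float], float] | None = None,
    pressure_range: tuple[float, float] = (120.0, 270.0),
    solute: SoluteProperties | None = None,
) -> tuple[float, float] | None:
    """Minimal pressure interval containing all pairwise isotherm crossings.

    Each fitted model predicts y2(P) along its isotherm on a 1-bar grid;
    sign changes of pairwise differences are bracketed and refined linearly.
    Returns None when no pair of isotherms intersects in range.
    """
    if len(isotherm_models) < 2:
        raise ValueError("need at least two isotherms")
    lo, hi = pressure_range
    if hi <= lo:
        raise ValueError("empty pressure range")
    if density_fn is None:
        from .synthetic_data import density_lookup

        density_fn = density_lookup
    grid = np.arange(lo, hi + 0.5, 1.0)
    curves = {}
    for T, fitted in isotherm_models.items():
        curves[T] = np.array(
            [predict_mole_fraction(fitted, (T, p, density_fn(T, p)), solute) for p in grid]
        )
    temps = sorted(curves)
    crossings: list[float] = []
    for i, t1 in enumerate(temps):
        for t2 in temps[i + 1 :]:
            diff = curves[t1] - curves[t2]
            sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
            for j in sign_change:
                d0, d1 = diff[j], diff[j + 1]
                frac = 0.0 if d1 == d0 else d0 / (d0 - d1)
                crossings.append(float(grid[j] + frac))
    if not crossings:
        return None
    return min(crossings), max(crossings)


def mst_self_consistency(dataset: SolubilityDataset, mst_fit: FittedModel) -> dict:
    """Collapse test of all isotherms onto one line in the MST plane.

    With the fitted MST coefficients (a0, a1, a2), T ln(y2 P) - a2 T plotted
    against density must fall on the single line a0 + a1 rho for
    thermodynamically consistent data. Reports the regression line, its R^2,
    and per-temperature mean residuals.
    """
    if mst_fit.spec.name != "mst":
        raise ValueError("mst_self_consistency requires an MST fit")
    a2 = mst_fit.params[2]
    T = dataset.column("T")
    P = dataset.column("P")
    rho = dataset.column("rho")
    y2 = dataset.column("y2")
    lhs = T * np.log(y2 * P) - a2 * T
    rho_span = rho.max() - rho.min()
    reliable = rho_span > 1e-9 * max(abs(rho.max()), 1.0)
    if reliable:
        slope, intercept = np.polyfit(rho, lhs, 1)
        fitted_line = intercept + slope * rho
        ss_t = float(np.sum((lhs - lhs.mean()) ** 2))
        ss_e = float(np.sum((lhs - fitted_line) ** 2))
        r2_line = 1.0 - ss_e / ss_t if ss_t > 0 else 1.0
    else:
        slope = intercept = r2_line = float("nan")
        fitted_line = np.full_like(lhs, np.nan)
    residuals = lhs - fitted_line
    per_t = {float(t): float(np.mean(residuals[T == t])) for t in np.unique(T)}
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r2_line": float(r2_line),
        "per_T_residuals": per_t,
        "reliable": bool(reliable),
    }
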