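"""Peng-Robinson solid-fluid equilibrium with vdW2 mixing rules.

Solubility of a solid (2) in a supercritical solvent (1) follows from
equating the solid fugacity to its fugacity in the fluid phase:

    y2 = (P2_sub * phi2_sat) / (P * phi2_fluid(y2)) * exp[(P - P2_sub) v2 / (R T)]

with phi2_sat = 1 (the sublimation pressure is tiny) and the Poynting factor
pressurizing the solid reference state. phi2_fluid comes from the PR EoS with
quadratic (vdW2) mixing rules in both the attraction parameter a (correction
k12) and the covolume b (correction l12). Because b is composition dependent,
the partial fugacity coefficient carries the composition derivative
b_bar_i = 2 sum_j y_j b_ij - b in place of the usual b_ii.

Internally everything is SI (Pa, m^3/mol, K); pressures cross the module
boundary in bar and are converted by 1e5, molar volumes in cm^3/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_data import R_GAS, SolubilityDataset, SoluteProperties
from .fitstats import FitStatistics, OptimizerConfig, compute_statistics

BAR = 1e5  # Pa
SQRT2 = math.sqrt(2.0)

CO2_TC = 304.18  # K
CO2_PC = 73.8  # bar
CO2_OMEGA = 0.274


class NoPhysicalRootError(RuntimeError):
    """The PR cubic has no root larger than the covolume."""


class ConvergenceError(RuntimeError):
    """The solubility fixed point failed to converge; carries the trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class PurePrParams:
    """Pure-component PR parameters at one temperature (SI units)."""

    Tc: float
    Pc: float  # bar
    omega: float
    T: float
    a: float  # Pa m^6 / mol^2
    b: float  # m^3 / mol


@dataclass(frozen=True)
class EosBinary:
    co2: PurePrParams
    solute: PurePrParams
    k12: float = 0.0
    l12: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.k12) > 2 or abs(self.l12) > 2:
            raise ValueError("interaction corrections must satisfy |k12|, |l12| <= 2")


@dataclass(frozen=True)
class SolidEquilibriumInput:
    """State for one solubility solve: T (K), P (bar), psub (Pa), v_solid (cm^3/mol)."""

    T: float
    P: float
    psub: float
    v_solid: float
    phi_sat: float = 1.0

    def __post_init__(self) -> None:
        if self.psub <= 0:
            raise ValueError("sublimation pressure must be positive")
        if self.psub >= self.P * BAR:
            raise ValueError("sublimation pressure must be far below the system pressure")


def pure_pr_params(Tc: float, Pc: float, omega: float, T: float) -> PurePrParams:
    """Standard PR pure-component a(T) and b from critical constants (Pc in bar)."""
    if min(T, Tc, Pc) <= 0:
        raise ValueError("T, Tc, Pc must be positive")
    kappa = 0.37464 + 1.54226 * omega - 0.26992 * omega * omega
    alpha = (1.0 + kappa * (1.0 - math.sqrt(T / Tc))) ** 2
    pc_pa = Pc * BAR
    a = 0.45724 * R_GAS**2 * Tc**2 * alpha / pc_pa
    b = 0.07780 * R_GAS * Tc / pc_pa
    return PurePrParams(Tc=Tc, Pc=Pc, omega=omega, T=T, a=a, b=b)


def make_binary(solute: SoluteProperties, T: float, k12: float = 0.0, l12: float = 0.0) -> EosBinary:
    """CO2(1)-solute(2) pair at temperature T."""
    return EosBinary(
        co2=pure_pr_params(CO2_TC, CO2_PC, CO2_OMEGA, T),
        solute=pure_pr_params(solute.Tc, solute.Pc, solute.omega, T),
        k12=k12,
        l12=l12,
    )


def cross_terms(binary: EosBinary) -> tuple[float, float]:
    a11, a22 = binary.co2.a, binary.solute.a
    if a11 * a22 < 0:
        raise ValueError("a11*a22 must be non-negative for the geometric-mean cross term")
    a12 = (1.0 - binary.k12) * math.sqrt(a11 * a22)
    b12 = (1.0 - binary.l12) * 0.5 * (binary.co2.b + binary.solute.b)
    return a12, b12


def mix_vdw2(binary: EosBinary, y2: float) -> tuple[float, float]:
    """Quadratic vdW2 mixture a and b at solute mole fraction y2."""
    if not 0.0 <= y2 <= 1.0:
        raise ValueError("mole fraction must lie in [0, 1]")
    a12, b12 = cross_terms(binary)
    y1 = 1.0 - y2
    a = y1 * y1 * binary.co2.a + y2 * y2 * binary.solute.a + 2 * y1 * y2 * a12
    b = y1 * y1 * binary.co2.b + y2 * y2 * binary.solute.b + 2 * y1 * y2 * b12
    return a, b


def _cubic_z_roots(A: float, B: float) -> np.ndarray:
    """Real roots of the PR compressibility cubic."""
    coeffs = [1.0, -(1.0 - B), A - 3 * B * B - 2 * B, -(A * B - B * B - B**3)]
    roots = np.roots(coeffs)
    return np.sort(roots[np.abs(roots.imag) < 1e-11].real)


def _ln_phi_pseudo_pure(Z: float, A: float, B: float) -> float:
    """Mixture fugacity coefficient at fixed composition (for root selection)."""
    return (
        Z
        - 1.0
        - math.log(Z - B)
        - A / (2 * SQRT2 * B) * math.log((Z + (1 + SQRT2) * B) / (Z + (1 - SQRT2) * B))
    )


def solve_molar_volume(a_mix: float, b_mix: float, T: float, P: float) -> float:
    """Fluid-phase molar volume (m^3/mol) at T (K) and P (bar).

    Among real cubic roots with v > b the root of minimal Gibbs energy is
    selected (equivalently, minimal mixture fugacity at fixed composition).
    """
    if T <= 0 or P <= 0:
        raise ValueError("T and P must be positive")
    p_pa = P * BAR
    rt = R_GAS * T
    A = a_mix * p_pa / (rt * rt)
    B = b_mix * p_pa / rt
    zs = [z for z in _cubic_z_roots(A, B) if z > B]
    if not zs:
        raise NoPhysicalRootError(f"no root above the covolume at T={T} K, P={P} bar")
    if len(zs) == 1:
        z_sel = zs[0]
    else:
        z_sel = min(zs, key=lambda z: _ln_phi_pseudo_pure(z, A, B))
    return z_sel * rt / p_pa


def phi_solute(binary: EosBinary, T: float, P: float, y2: float) -> float:
    """Partial fugacity coefficient of the solute in the fluid mixture."""
    a_mix, b_mix = mix_vdw2(binary, y2)
    v = solve_molar_volume(a_mix, b_mix, T, P)
    p_pa = P * BAR
    rt = R_GAS * T
    Z = p_pa * v / rt
    A = a_mix * p_pa / (rt * rt)
    B = b_mix * p_pa / rt
    a12, b12 = cross_terms(binary)
    y1 = 1.0 - y2
    # composition derivatives of the quadratic mixing rules
    sum_a2 = y1 * a12 + y2 * binary.solute.a  # sum_j y_j a_2j
    b_bar2 = 2.0 * (y1 * b12 + y2 * binary.solute.b) - b_mix  # d(nb)/dn2
    ln_phi = (
        b_bar2 / b_mix * (Z - 1.0)
        - math.log(Z - B)
        - A
        / (2 * SQRT2 * B)
        * (2.0 * sum_a2 / a_mix - b_bar2 / b_mix)
        * math.log((Z + (1 + SQRT2) * B) / (Z + (1 - SQRT2) * B))
    )
    return math.exp(ln_phi)


def solve_solubility(
    inp: SolidEquilibriumInput,
    binary: EosBinary,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> float:
    """Solid-fluid equilibrium mole fraction by damped successive substitution.

    y2 <- 0.5*y2 + 0.5 * (psub*phi_sat)/(P*phi2(y2)) * Poynting, clamped to
    (0, 0.1); converged when the relative update falls below ``tol``.
    """
    p_pa = inp.P * BAR
    v2 = inp.v_solid * 1e-6  # cm^3/mol -> m^3/mol
    poynting = math.exp((p_pa - inp.psub) * v2 / (R_GAS * inp.T))
    prefactor = inp.psub * inp.phi_sat / p_pa * poynting
    y = min(max(inp.psub / p_pa * 1e3, 1e-15), 0.05)
    trace = []
    for _ in range(max_iter):
        try:
            phi = phi_solute(binary, inp.T, inp.P, y)
        except OverflowError:
            raise ConvergenceError("fugacity coefficient overflowed", trace=trace) from None
        if phi <= 0 or not math.isfinite(phi):
            raise ConvergenceError("fugacity coefficient underflowed to zero", trace=trace)
        y_new = prefactor / phi
        y_new = min(max(y_new, 1e-20), 0.1)
        y_next = 0.5 * y + 0.5 * y_new
        trace.append(y_next)
        if abs(y_next - y) <= tol * max(y, 1e-300):
            return y_next
        y = y_next
    raise ConvergenceError(
        f"solubility fixed point did not converge in {max_iter} iterations", trace=trace
    )


def isotherm_psub(solute: SoluteProperties, T: float) -> float:
    """Tabulated sublimation pressure at T, falling back to Ambrose-Walton."""
    if T in solute.psub:
        return solute.psub[T]
    return ambrose_walton_psub(solute.Tc, solute.Pc, solute.omega, T)


def predict_isotherm(
    dataset_isotherm: SolubilityDataset,
    solute: SoluteProperties,
    k12: float,
    l12: float,
    psub: float | None = None,
    tol: float = 1e-10,
) -> np.ndarray:
    """PR-vdW2 solubility at each pressure of a single-temperature subset."""
    temps = dataset_isotherm.temperatures
    if len(temps) != 1:
        raise ValueError("predict_isotherm needs a single-temperature subset")
    T = temps[0]
    psub = isotherm_psub(solute, T) if psub is None else psub
    binary = make_binary(solute, T, k12, l12)
    out = []
    for rec in dataset_isotherm.records:
        inp = SolidEquilibriumInput(T=T, P=rec.P, psub=psub, v_solid=solute.v_molar)
        out.append(solve_solubility(inp, binary, tol=tol))
    return np.array(out)


def fit_interaction_params(
    dataset_isotherm: SolubilityDataset,
    solute: SoluteProperties,
    config: OptimizerConfig | None = None,
    psub: float | None = None,
    grid_step: float = 0.05,
    grid_range: tuple[float, float] = (-1.0, 1.0),
) -> tuple[float, float, FitStatistics]:
    """Regress (k12, l12) on one isotherm by coarse grid search + local polish.

    The objective is the summed relative deviation OF = sum |y_exp - y_calc| /
    y_exp; the strongly nonconvex surface makes the grid stage necessary. Fit
    statistics use the AARD definition with Z = 2.
    """
    from scipy.optimize import minimize

    temps = dataset_isotherm.temperatures
    if len(temps) != 1:
        raise ValueError("fit_interaction_params needs a single-temperature subset")
    if len(dataset_isotherm) < 3:
        raise ValueError("need at least 3 points on the isotherm")
    config = config or OptimizerConfig()
    y_exp = dataset_isotherm.column("y2")

    def objective(kl, tol=1e-8) -> float:
        k, l = float(kl[0]), float(kl[1])
        if abs(k) > 2 or abs(l) > 2:
            return math.inf
        try:
            y_calc = predict_isotherm(dataset_isotherm, solute, k, l, psub=psub, tol=tol)
        except (NoPhysicalRootError, ConvergenceError, OverflowError, ZeroDivisionError):
            return math.inf
        return float(np.sum(np.abs(y_exp - y_calc) / y_exp))

    grid = np.arange(grid_range[0], grid_range[1] + 0.5 * grid_step, grid_step)
    nodes = []
    for k in grid:
        for l in grid:
            val = objective((k, l))
            if math.isfinite(val):
                nodes.append((val, float(k), float(l)))
    if not nodes:
        raise RuntimeError("PR solubility solver failed on every grid node")
    nodes.sort()
    # polish the best few nodes: the objective funnel is narrow and curved,
    # so the global basin is not always under the single best node
    k12, l12, best_of = nodes[0][1], nodes[0][2], nodes[0][0]
    for _, k0, l0 in nodes[:4]:
        x = np.array([k0, l0])
        fx = objective(x)
        for _ in range(5):  # restart the simplex until it stops improving
            res = minimize(
                objective,
                x,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 1000},
            )
            if math.isfinite(res.fun) and res.fun < fx - 1e-14:
                x, fx = np.asarray(res.x, float), float(res.fun)
            else:
                break
        if fx < best_of:
            k12, l12, best_of = float(x[0]), float(x[1]), fx
    y_calc = predict_isotherm(dataset_isotherm, solute, k12, l12, psub=psub)
    stats = compute_statistics(y_exp, y_calc, Z=2, Q=2)
    return k12, l12, stats


# Ambrose-Walton corresponding-states vapor/sublimation pressure.
# Wagner-form functions of tau = 1 - T/Tc:
def _aw_f0(tau: float, tr: float) -> float:
    return (
        -5.97616 * tau + 1.29874 * tau**1.5 - 0.60394 * tau**2.5 - 1.06841 * tau**5
    ) / tr


def _aw_f1(tau: float, tr: float) -> float:
    return (
        -5.03365 * tau + 1.11505 * tau**1.5 - 5.41217 * tau**2.5 - 7.46628 * tau**5
    ) / tr


def _aw_f2(tau: float, tr: float) -> float:
    return (
        -0.64771 * tau + 2.41539 * tau**1.5 - 4.26979 * tau**2.5 + 3.25259 * tau**5
    ) / tr


def ambrose_walton_psub(Tc: float, Pc: float, omega: float, T: float) -> float:
    """Vapor/sublimation pressure (Pa) from critical constants (Pc in bar).

    ln(P/Pc) = f0 + omega*f1 + omega^2*f2 with the Ambrose-Walton Wagner-form
    corresponding-states functions; valid for 0 < T < Tc.
    """
    if not 0 < T < Tc:
        raise ValueError(f"require 0 < T < Tc; got T={T}, Tc={Tc}")
    tr = T / Tc
    tau = 1.0 - tr
    ln_pr = _aw_f0(tau, tr) + omega * _aw_f1(tau, tr) + omega * omega * _aw_f2(tau, tr)
    return Pc * BAR * math.exp(ln_pr)
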