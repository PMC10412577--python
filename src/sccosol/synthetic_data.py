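"""Synthetic solubility surfaces and multi-drug feature tables.

The generators emulate the structure of static-measurement studies: four
isotherms (308-338 K) by six pressures (120-270 bar), mole fractions following
a Chrastil-type density law with multiplicative lognormal noise (solubility
spans orders of magnitude, so the natural error model is relative), and
multi-drug tables with six physicochemical features per record for the ML
harness. Densities interpolate the packaged CO2 density grid bilinearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import RegularGridInterpolator

import pandas as pd

from .core_data import (
    M_CO2,
    SolubilityDataset,
    SolubilityRecord,
    SoluteProperties,
    nhm_fixture,
    nhm_solute,
)
from .density_models import (
    DensityModelSpec,
    FittedModel,
    get_spec,
    predict_mole_fraction,
)


class ExtrapolationError(ValueError):
    """Density query outside the packaged (T, P) grid."""


def _density_interpolator() -> RegularGridInterpolator:
    data, _ = nhm_fixture()
    temps = np.array(data.temperatures)
    pressures = np.array(sorted({r.P for r in data.records}))
    grid = np.empty((temps.size, pressures.size))
    lookup = {(r.T, r.P): r.rho for r in data.records}
    for i, t in enumerate(temps):
        for j, p in enumerate(pressures):
            grid[i, j] = lookup[(t, p)]
    return RegularGridInterpolator((temps, pressures), grid, method="linear", bounds_error=True)


_INTERP: RegularGridInterpolator | None = None


def density_lookup(T: float, P: float) -> float:
    """Bilinear interpolation of the packaged CO2 density grid (kg/m^3).

    Exact at the 24 tabulated nodes; queries outside the 308-338 K x
    120-270 bar hull raise :class:`ExtrapolationError`.
    """
    global _INTERP
    if _INTERP is None:
        _INTERP = _density_interpolator()
    try:
        return float(_INTERP((T, P)))
    except ValueError as exc:
        raise ExtrapolationError(f"(T={T}, P={P}) outside the packaged density grid") from exc


DEFAULT_T_GRID = (308.0, 318.0, 328.0, 338.0)
DEFAULT_P_GRID = (120.0, 150.0, 180.0, 210.0, 240.0, 270.0)


@dataclass(frozen=True)
class SurfaceSpec:
    """Ground truth for one synthetic solubility surface."""

    model: DensityModelSpec
    params: tuple[float, ...]
    T_grid: tuple[float, ...] = DEFAULT_T_GRID
    P_grid: tuple[float, ...] = DEFAULT_P_GRID
    density_fn: Callable[[float, float], float] = density_lookup
    noise_cv: float = 0.0
    seed: int = 0
    solute: SoluteProperties = field(default_factory=nhm_solute)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not self.T_grid or not self.P_grid:
            raise ValueError("grids must be non-empty")


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2), size=n)


def mole_fraction_to_concentration(y2: float, rho: float, Mw: float) -> float:
    """Invert the dilute-sampling conversion: c (g/L) from y2 and density."""
    return Mw * (rho / M_CO2) * y2 / (1.0 - y2)


def generate_surface(spec: SurfaceSpec) -> SolubilityDataset:
    """Solubility dataset from a ground-truth model plus lognormal noise.

    The S column is derived from the (noisy) mole fraction through the dilute
    conversion, keeping the two columns mutually consistent by construction.
    """
    rng = np.random.default_rng(spec.seed)
    fitted = FittedModel(spec=spec.model, params=spec.params)
    cells = [(t, p) for t in spec.T_grid for p in spec.P_grid]
    noise = _lognormal_factors(rng, spec.noise_cv, len(cells))
    records = []
    for (t, p), fac in zip(cells, noise):
        rho = spec.density_fn(t, p)
        try:
            y2 = predict_mole_fraction(fitted, (t, p, rho), spec.solute)
        except Exception as exc:
            raise RuntimeError(f"model evaluation failed at (T={t}, P={p})") from exc
        y2 = y2 * fac
        records.append(
            SolubilityRecord(
                T=t,
                P=p,
                rho=rho,
                y2=y2,
                S=mole_fraction_to_concentration(y2, rho, spec.solute.Mw),
            )
        )
    return SolubilityDataset(tuple(records), solute=spec.solute, label=f"synthetic-{spec.model.name}")


def chrastil_surface_spec(
    seed: int = 0,
    noise_cv: float = 0.05,
    rng: np.random.Generator | None = None,
) -> SurfaceSpec:
    """Random Chrastil ground truth in the physically realistic band.

    a0 in [4, 7], a1 in [-9000, -4000] K; a2 pinned so the mid-grid mole
    fraction lands in the 1e-7..1e-5 band typical of poorly soluble drugs.
    """
    rng = rng or np.random.default_rng(seed)
    model = get_spec("chrastil")
    solute = nhm_solute()
    a0 = rng.uniform(4.0, 7.0)
    a1 = rng.uniform(-9000.0, -4000.0)
    t_mid, p_mid = 318.0, 210.0
    rho_mid = density_lookup(t_mid, p_mid)
    y_mid = 10 ** rng.uniform(-6.5, -5.5)
    c_mid = mole_fraction_to_concentration(y_mid, rho_mid, solute.Mw)
    a2 = math.log(c_mid) - a0 * math.log(rho_mid) - a1 / t_mid
    return SurfaceSpec(
        model=model, params=(a0, a1, a2), noise_cv=noise_cv, seed=seed, solute=solute
    )


#: feature schema shared with ml_harness
FEATURE_COLUMNS = ["T_K", "P_bar", "rho_kg_m3", "dH_fus_J_mol", "Tm_K", "psub_Pa"]
TARGET_COLUMN = "y2"


def generate_multidrug_table(
    n_drugs: int, seed: int = 0, noise_cv: float = 0.05
) -> pd.DataFrame:
    """Multi-drug solubility feature table (24 records per drug).

    Each drug gets sampled melting properties (Tm, dH_fus by Walden's rule),
    a Clausius-Clapeyron sublimation-pressure law, and a Chrastil-law
    solubility surface; 18 drugs reproduce the 432-row benchmark layout.
    """
    if n_drugs < 1:
        raise ValueError("need at least one drug")
    rng = np.random.default_rng(seed)
    frames = []
    for d in range(n_drugs):
        surface = chrastil_surface_spec(seed=int(rng.integers(0, 2**31 - 1)), noise_cv=noise_cv,
                                        rng=rng)
        data = generate_surface(surface)
        tm = rng.uniform(400.0, 520.0)
        dh_fus = 56.5 * tm
        b_sub = rng.uniform(8000.0, 12000.0)
        psub_308 = 10 ** rng.uniform(-4.0, -1.5)
        a_sub = math.log(psub_308) + b_sub / 308.0
        frame = data.to_frame()[["T_K", "P_bar", "rho_kg_m3", "y2"]].copy()
        frame["dH_fus_J_mol"] = dh_fus
        frame["Tm_K"] = tm
        frame["psub_Pa"] = np.exp(a_sub - b_sub / frame["T_K"])
        frame["drug"] = f"drug_{d:02d}"
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    return table[["drug"] + FEATURE_COLUMNS + [TARGET_COLUMN]]
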