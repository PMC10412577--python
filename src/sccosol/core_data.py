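"""Data model for static solubility measurements in supercritical CO2.

Units are locked package-wide: temperature K, pressure bar, CO2 density
kg/m^3 (numerically equal to g/L), solubility and vial concentration g/L,
mole fraction dimensionless, enthalpy kJ/mol, R = 8.314 J/(mol K).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

R_GAS = 8.314  # J / (mol K)
M_CO2 = 44.01  # g/mol
RHO_C_CO2 = 467.6  # critical density of CO2, kg/m^3

CSV_COLUMNS = ["T_K", "P_bar", "rho_kg_m3", "y2", "S_g_L", "sd_mean", "U_expanded"]


class SchemaError(ValueError):
    """Raised when a solubility table violates the CSV schema."""


class InvalidGeometryError(ValueError):
    """Raised for non-physical sampling-geometry volumes."""


class InvalidDensityError(ValueError):
    """Raised for a non-positive CO2 density."""


@dataclass(frozen=True)
class SolubilityRecord:
    """One equilibrium observation: (T, P, rho, y2, S) plus uncertainties."""

    T: float
    P: float
    rho: float
    y2: float
    S: float
    sd_mean: float | None = None
    U: float | None = None

    def __post_init__(self) -> None:
        if not (self.T > 0 and self.P > 0 and self.rho > 0):
            raise ValueError(f"T, P, rho must be positive; got {(self.T, self.P, self.rho)}")
        if not (0 < self.y2 < 1):
            raise ValueError(f"mole fraction must lie in (0, 1); got {self.y2}")
        if not self.S > 0:
            raise ValueError(f"solubility must be positive; got {self.S}")
        if self.sd_mean is not None and self.sd_mean < 0:
            raise ValueError("sd_mean must be non-negative")
        if self.U is not None and self.sd_mean is not None and self.U < self.sd_mean:
            raise ValueError("expanded uncertainty U must be >= sd_mean")


@dataclass(frozen=True)
class SoluteProperties:
    """Physicochemical constants of the solid solute.

    ``psub`` maps temperature (K) to sublimation pressure (Pa); values must
    increase strictly with temperature (Clausius-Clapeyron behaviour).
    """

    name: str
    formula: str
    Mw: float
    Tm: float
    Tb: float
    Tc: float
    Pc: float
    omega: float
    v_molar: float
    psub: dict[float, float] = field(default_factory=dict)
    lambda_max: float | None = None

    def __post_init__(self) -> None:
        if self.Mw <= 0 or self.Pc <= 0 or self.omega <= 0 or self.v_molar <= 0:
            raise ValueError("Mw, Pc, omega, v_molar must be positive")
        if not (self.Tc > self.Tb > 0):
            raise ValueError("require Tc > Tb > 0")
        temps = sorted(self.psub)
        vals = [self.psub[t] for t in temps]
        if any(v <= 0 for v in vals):
            raise ValueError("sublimation pressures must be positive")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("sublimation pressure must increase strictly with T")


@dataclass(frozen=True)
class SolubilityDataset:
    """Ordered collection of records for one solute, sorted by (T, P)."""

    records: tuple[SolubilityRecord, ...]
    solute: SoluteProperties | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("dataset must be non-empty")
        keys = [(r.T, r.P) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (T, P) pairs in dataset")
        object.__setattr__(self, "records", tuple(sorted(self.records, key=lambda r: (r.T, r.P))))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(sorted({r.T for r in self.records}))

    def isotherm(self, T: float) -> "SolubilityDataset":
        recs = tuple(r for r in self.records if r.T == T)
        if not recs:
            raise KeyError(f"no records at T={T}")
        return SolubilityDataset(recs, self.solute, f"{self.label}@{T}K")

    def column(self, name: str):
        import numpy as np

        return np.array([getattr(r, name) for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_K": [r.T for r in self.records],
                "P_bar": [r.P for r in self.records],
                "rho_kg_m3": [r.rho for r in self.records],
                "y2": [r.y2 for r in self.records],
                "S_g_L": [r.S for r in self.records],
                "sd_mean": [r.sd_mean for r in self.records],
                "U_expanded": [r.U for r in self.records],
            }
        )


@dataclass(frozen=True)
class MeasurementGeometry:
    """Static-sampling geometry: collection-vial and sampling-loop volumes (L)."""

    Vs: float = 5e-3
    Vl: float = 600e-6
    M_co2: float = M_CO2

    def __post_init__(self) -> None:
        if not (self.Vs > self.Vl > 0):
            raise InvalidGeometryError(f"require Vs > Vl > 0; got Vs={self.Vs}, Vl={self.Vl}")


@dataclass(frozen=True)
class UncertaintyBudget:
    """Components (sensitivity P_i, standard uncertainty u_i, nominal x_i)."""

    components: tuple[tuple[float, float, float], ...]
    coverage_k: float = 2.0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("uncertainty budget must be non-empty")
        if self.coverage_k <= 0:
            raise ValueError("coverage factor must be positive")
        for i, (_, u, _x) in enumerate(self.components):
            if u < 0:
                raise ValueError(f"component {i}: standard uncertainty must be >= 0")


def concentration_to_solubility(Cs: float, geom: MeasurementGeometry) -> float:
    """Equilibrium solubility S (g/L) from the collection-vial concentration.

    The loop volume Vl of saturated fluid is flushed into a vial holding the
    solution volume Vs, so S = Cs * Vs / Vl.
    """
    if Cs < 0:
        raise ValueError("vial concentration must be non-negative")
    return Cs * geom.Vs / geom.Vl


def solubility_to_concentration(S: float, geom: MeasurementGeometry) -> float:
    """Inverse of :func:`concentration_to_solubility`."""
    if S < 0:
        raise ValueError("solubility must be non-negative")
    return S * geom.Vl / geom.Vs


def concentration_to_mole_fraction(
    Cs: float, rho: float, solute: SoluteProperties, geom: MeasurementGeometry
) -> float:
    """Mole fraction y2 from the vial concentration and CO2 density (g/L).

    n_solute = Cs*Vs/Mw, n_CO2 = Vl*rho/M_CO2, y2 = n_solute/(n_solute+n_CO2).
    """
    if Cs < 0:
        raise ValueError("vial concentration must be non-negative")
    if rho <= 0:
        raise InvalidDensityError(f"CO2 density must be positive; got {rho}")
    n_solute = Cs * geom.Vs / solute.Mw
    n_co2 = geom.Vl * rho / geom.M_co2
    return n_solute / (n_solute + n_co2)


def propagate_uncertainty(budget: UncertaintyBudget, y: float) -> tuple[float, float]:
    """Relative combined standard uncertainty and expanded uncertainty.

    u_rel = sqrt(sum_i (P_i * u(x_i) / x_i)^2);  U = k * u_rel * y.
    """
    total = 0.0
    for i, (p, u, x) in enumerate(budget.components):
        if x == 0:
            raise ZeroDivisionError(f"uncertainty component {i} has nominal value 0")
        total += (p * u / x) ** 2
    u_rel = total**0.5
    return u_rel, budget.coverage_k * u_rel * y


def _parse_cell(value, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, str) and not value.strip()) or pd.isna(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}, column {column!r}: non-numeric cell {value!r}") from None


def load_dataset(path: str | Path, solute: SoluteProperties | None = None) -> SolubilityDataset:
    """Read a solubility table from the canonical CSV schema.

    Header must be exactly ``T_K,P_bar,rho_kg_m3,y2,S_g_L,sd_mean,U_expanded``
    (the two uncertainty columns may be empty). Errors cite 1-based data rows.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    records = []
    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        vals = {c: _parse_cell(getattr(row, c), idx, c) for c in CSV_COLUMNS}
        for c in ("T_K", "P_bar", "rho_kg_m3", "y2", "S_g_L"):
            if vals[c] is None:
                raise SchemaError(f"row {idx}, column {c!r}: value required")
        records.append(
            SolubilityRecord(
                T=vals["T_K"],
                P=vals["P_bar"],
                rho=vals["rho_kg_m3"],
                y2=vals["y2"],
                S=vals["S_g_L"],
                sd_mean=vals["sd_mean"],
                U=vals["U_expanded"],
            )
        )
    keys = [(r.T, r.P) for r in records]
    dupes = {k for k in keys if keys.count(k) > 1}
    if dupes:
        raise SchemaError(f"{path}: duplicate (T, P) pairs {sorted(dupes)}")
    return SolubilityDataset(tuple(records), solute=solute, label=path.stem)


def save_dataset(dataset: SolubilityDataset, path: str | Path) -> None:
    """Write a dataset in the canonical CSV schema (full float precision)."""
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, float_format="%.17g")


def load_solute(path: str | Path) -> SoluteProperties:
    """Read solute properties from a YAML or JSON record."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data["psub"] = {float(k): float(v) for k, v in data.get("psub", {}).items()}
    return SoluteProperties(**data)


def save_solute(solute: SoluteProperties, path: str | Path) -> None:
    path = Path(path)
    data = {
        "name": solute.name,
        "formula": solute.formula,
        "Mw": solute.Mw,
        "Tm": solute.Tm,
        "Tb": solute.Tb,
        "Tc": solute.Tc,
        "Pc": solute.Pc,
        "omega": solute.omega,
        "v_molar": solute.v_molar,
        "psub": {k: v for k, v in solute.psub.items()},
        "lambda_max": solute.lambda_max,
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))


# 24-point nilotinib hydrochloride monohydrate (NHM) dataset: four isotherms
# (308-338 K) x six pressures (120-270 bar). y2/sd/U columns are stored in
# mole-fraction units (the source table prints them scaled by 1e5). The
# printed y2 and S columns are kept verbatim; they are NOT mutually
# consistent with the sampling-geometry conversion equations (recomputing y2
# from S gives ~1.5x the printed y2 on every row), so both are preserved and
# model fitting targets the stored columns.
_NHM_ROWS = [
    # (T_K, P_bar, rho_kg_m3, y2*1e5, S_g_L, sd*1e5, U*1e5)
    (308, 120, 769, 0.104, 0.016, 0.002, 0.006),
    (308, 150, 817, 0.125, 0.020, 0.001, 0.006),
    (308, 180, 849, 0.151, 0.025, 0.002, 0.007),
    (308, 210, 875, 0.195, 0.034, 0.001, 0.009),
    (308, 240, 896, 0.219, 0.039, 0.003, 0.011),
    (308, 270, 914, 0.270, 0.049, 0.002, 0.012),
    (318, 120, 661, 0.071, 0.009, 0.002, 0.005),
    (318, 150, 744, 0.141, 0.021, 0.002, 0.007),
    (318, 180, 791, 0.199, 0.031, 0.002, 0.009),
    (318, 210, 824, 0.228, 0.037, 0.003, 0.011),
    (318, 240, 851, 0.269, 0.046, 0.003, 0.013),
    (318, 270, 872, 0.313, 0.054, 0.004, 0.016),
    (328, 120, 509, 0.051, 0.005, 0.002, 0.004),
    (328, 150, 656, 0.191, 0.025, 0.001, 0.008),
    (328, 180, 725, 0.239, 0.034, 0.002, 0.011),
    (328, 210, 769, 0.313, 0.048, 0.003, 0.015),
    (328, 240, 802, 0.433, 0.069, 0.004, 0.020),
    (328, 270, 829, 0.514, 0.085, 0.004, 0.024),
    (338, 120, 388, 0.032, 0.002, 0.001, 0.002),
    (338, 150, 557, 0.252, 0.028, 0.001, 0.011),
    (338, 180, 652, 0.355, 0.046, 0.003, 0.017),
    (338, 210, 710, 0.424, 0.060, 0.004, 0.021),
    (338, 240, 751, 0.563, 0.084, 0.004, 0.026),
    (338, 270, 783, 0.599, 0.094, 0.006, 0.029),
]


def nhm_solute() -> SoluteProperties:
    """Physicochemical properties of nilotinib hydrochloride monohydrate.

    Critical constants are group-contribution estimates; sublimation
    pressures are Ambrose-Walton corresponding-states values per isotherm.
    """
    return SoluteProperties(
        name="nilotinib hydrochloride monohydrate",
        formula="C28H25ClF3N7O2.HCl.H2O",
        Mw=584.0,
        Tm=480.15,
        Tb=725.640,
        Tc=936.444,
        Pc=11.77822,
        omega=0.5913,
        v_molar=376.8,
        psub={308.0: 4.0739e-4, 318.0: 1.4e-3, 328.0: 4.3e-3, 338.0: 1.25e-2},
        lambda_max=270.0,
    )


def nhm_fixture() -> tuple[SolubilityDataset, SoluteProperties]:
    """Packaged NHM dataset (24 records) with its solute properties."""
    solute = nhm_solute()
    records = tuple(
        SolubilityRecord(T=t, P=p, rho=rho, y2=y * 1e-5, S=s, sd_mean=sd * 1e-5, U=u * 1e-5)
        for (t, p, rho, y, s, sd, u) in _NHM_ROWS
    )
    return SolubilityDataset(records, solute=solute, label="NHM"), solute
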