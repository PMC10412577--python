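"""Ten density-based empirical/semi-empirical solubility correlations.

Every model here is log-linear in its adjustable parameters: a linear
predictor g = X(T, P, rho) . a is mapped through a fixed inverse link to the
model's native output (solute concentration in g/L, mole fraction y2, or the
Mendez-Santiago-Teja combination T*ln(y2*P)). That structure is exploited by
the fitting pipeline: ordinary least squares in the linear space gives the
starting point, direct AARD minimization polishes it.

Pressure enters the formulas in bar and temperature in K, exactly as
tabulated in the source data; no SI conversion happens inside a formula.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .core_data import M_CO2, RHO_C_CO2, SolubilityDataset, SoluteProperties

#: output spaces
CONCENTRATION = "concentration_gL"
MOLE_FRACTION = "mole_fraction"
T_LN_Y2P = "T_ln_y2P"


class ArityError(ValueError):
    """Parameter vector length does not match the model."""


class MissingPropertyError(ValueError):
    """A unit conversion needs a solute property that was not supplied."""


@dataclass(frozen=True)
class DensityModelSpec:
    """One named correlation: arity, output space and reference constants."""

    name: str
    n_params: int
    output_space: str
    constants: dict = field(default_factory=dict)

    def design_row(self, T: float, P: float, rho: float) -> np.ndarray:
        return _DESIGNS[self.name](T, P, rho, self.constants)

    def design_matrix(self, T, P, rho) -> np.ndarray:
        T, P, rho = np.broadcast_arrays(
            np.asarray(T, float), np.asarray(P, float), np.asarray(rho, float)
        )
        return np.array(
            [self.design_row(t, p, r) for t, p, r in zip(T.ravel(), P.ravel(), rho.ravel())]
        )

    def linear_target(self, dataset: SolubilityDataset) -> np.ndarray:
        """Observed data transformed to the model's linear-predictor space."""
        y2 = dataset.column("y2")
        S = dataset.column("S")
        T = dataset.column("T")
        P = dataset.column("P")
        if self.output_space == CONCENTRATION:
            return np.log(S)
        if self.output_space == T_LN_Y2P:
            return T * np.log(y2 * P)
        if self.name == "bartle":
            return np.log(y2 * P / self.constants["P_ref"])
        return np.log(y2)

    def comparison_observed(self, dataset: SolubilityDataset) -> np.ndarray:
        """Observed column the model's AARD is measured against."""
        return dataset.column("S" if self.output_space == CONCENTRATION else "y2")


def _chrastil(T, P, rho, c):
    return np.array([math.log(rho), 1.0 / T, 1.0])


def _bian(T, P, rho, c):
    lr = math.log(rho)
    return np.array([lr, rho * lr, 1.0 / T, rho / T, 1.0])


def _gordillo(T, P, rho, c):
    return np.array([1.0, P, P * P, P * T, T, T * T])


def _jafari_nejad(T, P, rho, c):
    return np.array([1.0, P * P, T * T, math.log(rho)])


def _garlapati_madras(T, P, rho, c):
    lr = math.log(rho)
    return np.array([1.0, lr, rho * lr, 1.0 / T, math.log(rho * T)])


def _mst(T, P, rho, c):
    return np.array([1.0, rho, T])


def _jouyban(T, P, rho, c):
    return np.array([1.0, rho, P * P, P * T, T / P, math.log(rho) / T])


def _sparks(T, P, rho, c):
    rr = rho / c["rho_c_co2"]
    lrr = math.log(rr)
    return np.array([lrr, rr * lrr, 1.0, 1.0 / T])


def _bartle(T, P, rho, c):
    return np.array([1.0, 1.0 / T, rho - c["rho_ref"]])


def _sodeifian(T, P, rho, c):
    lr = math.log(rho)
    return np.array([1.0, P * P / T, math.log(rho * T), rho * lr, P * math.log(T), lr / T])


_DESIGNS: dict[str, Callable] = {
    "chrastil": _chrastil,
    "bian": _bian,
    "gordillo": _gordillo,
    "jafari_nejad": _jafari_nejad,
    "garlapati_madras": _garlapati_madras,
    "mst": _mst,
    "jouyban": _jouyban,
    "sparks": _sparks,
    "bartle": _bartle,
    "sodeifian": _sodeifian,
}

_SPECS: dict[str, DensityModelSpec] = {
    "chrastil": DensityModelSpec("chrastil", 3, CONCENTRATION),
    "bian": DensityModelSpec("bian", 5, MOLE_FRACTION),
    "gordillo": DensityModelSpec("gordillo", 6, MOLE_FRACTION),
    "jafari_nejad": DensityModelSpec("jafari_nejad", 4, MOLE_FRACTION),
    "garlapati_madras": DensityModelSpec("garlapati_madras", 5, MOLE_FRACTION),
    "mst": DensityModelSpec("mst", 3, T_LN_Y2P),
    "jouyban": DensityModelSpec("jouyban", 6, MOLE_FRACTION),
    "sparks": DensityModelSpec("sparks", 4, CONCENTRATION, {"rho_c_co2": RHO_C_CO2}),
    "bartle": DensityModelSpec("bartle", 3, MOLE_FRACTION, {"P_ref": 1.0, "rho_ref": 700.0}),
    "sodeifian": DensityModelSpec("sodeifian", 6, MOLE_FRACTION),
}


def model_registry() -> list[DensityModelSpec]:
    """All ten correlation specs, in a fixed canonical order."""
    order = [
        "chrastil",
        "bian",
        "gordillo",
        "jafari_nejad",
        "garlapati_madras",
        "mst",
        "jouyban",
        "sparks",
        "bartle",
        "sodeifian",
    ]
    return [_SPECS[n] for n in order]


def get_spec(name: str) -> DensityModelSpec:
    try:
        return _SPECS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; valid: {sorted(_SPECS)}") from None


def evaluate_model(
    spec: DensityModelSpec, params: Sequence[float], T: float, P: float, rho: float
) -> float:
    """Closed-form evaluation of the named formula in its native output space."""
    if len(params) != spec.n_params:
        raise ArityError(f"{spec.name} takes {spec.n_params} parameters, got {len(params)}")
    if T <= 0 or P <= 0:
        raise ValueError("T and P must be positive")
    if rho <= 0:
        raise ValueError(f"density must be positive for {spec.name}; got {rho}")
    g = float(np.dot(spec.design_row(T, P, rho), np.asarray(params, float)))
    if spec.output_space == T_LN_Y2P:
        return g
    if spec.name == "bartle":
        return math.exp(g) * spec.constants["P_ref"] / P
    return math.exp(g)


def output_to_mole_fraction(
    spec: DensityModelSpec,
    value: float,
    T: float,
    P: float,
    rho: float,
    solute: SoluteProperties | None = None,
) -> float:
    """Convert a native-space model output to mole fraction y2."""
    if spec.output_space == MOLE_FRACTION:
        return value
    if spec.output_space == T_LN_Y2P:
        return math.exp(value / T) / P
    if solute is None:
        raise MissingPropertyError(
            f"{spec.name} predicts concentration; solute molar mass required for y2"
        )
    n_solute = value / solute.Mw
    return n_solute / (n_solute + rho / M_CO2)


@dataclass(frozen=True)
class FittedModel:
    """A correlation with its fitted parameter vector and fit statistics."""

    spec: DensityModelSpec
    params: tuple[float, ...]
    stats: object | None = None
    dataset_label: str = ""

    def __post_init__(self) -> None:
        if len(self.params) != self.spec.n_params:
            raise ArityError(
                f"{self.spec.name} takes {self.spec.n_params} parameters, got {len(self.params)}"
            )
        if not all(math.isfinite(p) for p in self.params):
            raise ValueError("fitted parameters must be finite")

    def evaluate(self, T: float, P: float, rho: float) -> float:
        return evaluate_model(self.spec, self.params, T, P, rho)

    def to_json(self) -> str:
        from dataclasses import asdict

        stats = asdict(self.stats) if hasattr(self.stats, "__dataclass_fields__") else self.stats
        return json.dumps(
            {
                "model": self.spec.name,
                "params": list(self.params),
                "constants": self.spec.constants,
                "stats": stats,
                "dataset_label": self.dataset_label,
            },
            indent=2,
        )


def predict_mole_fraction(
    fitted: FittedModel,
    record_context: tuple[float, float, float],
    solute: SoluteProperties | None = None,
) -> float:
    """Predicted y2 at (T, P, rho), whatever the model's native space."""
    T, P, rho = record_context
    value = fitted.evaluate(T, P, rho)
    return output_to_mole_fraction(fitted.spec, value, T, P, rho, solute)


def save_fitted(fitted: FittedModel, path: str | Path) -> None:
    Path(path).write_text(fitted.to_json())
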