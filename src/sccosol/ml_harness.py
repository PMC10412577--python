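"""Pluggable train/test evaluation protocol for solubility regression.

Feature tables carry exactly six physicochemical predictors per record
(temperature, pressure, CO2 density, fusion enthalpy, melting temperature,
sublimation pressure) and the mole-fraction target. Model families are
injected through the usual fit/predict contract rather than implemented
here; the harness owns the split arithmetic and the held-out metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

FEATURE_COLUMNS = ["T_K", "P_bar", "rho_kg_m3", "dH_fus_J_mol", "Tm_K", "psub_Pa"]
TARGET_COLUMN = "y2"
MODEL_FAMILIES = ("tree_ensemble", "single_tree", "shallow_net", "deep_net")


class RegressorError(RuntimeError):
    """A plugged-in regressor failed; carries its family label."""

    def __init__(self, family: str, cause: Exception):
        super().__init__(f"regressor family {family!r} failed: {cause}")
        self.family = family


@dataclass(frozen=True)
class EvalResult:
    mae: float
    mse: float
    r2: float
    model_family: str
    split_seed: int

    def __post_init__(self) -> None:
        if self.mae < 0 or self.mse < 0 or self.r2 > 1:
            raise ValueError("require mae, mse >= 0 and r2 <= 1")


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FEATURE_COLUMNS + [TARGET_COLUMN] if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    sub = table[FEATURE_COLUMNS + [TARGET_COLUMN]]
    if sub.isna().any().any():
        raise ValueError("feature table contains missing values")
    if (table[TARGET_COLUMN] <= 0).any():
        raise ValueError("target mole fractions must be positive")
    return table


def build_split(
    table: pd.DataFrame,
    train_fraction: float = 0.75,
    seed: int = 0,
    group_by_drug: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split; floor(train_fraction*n) rows train.

    Row-wise by default (the benchmark protocol); ``group_by_drug`` keeps all
    records of a drug on one side for leakage-aware evaluation.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(table) == 0:
        raise ValueError("feature table is empty")
    rng = np.random.default_rng(seed)
    if group_by_drug:
        if "drug" not in table.columns:
            raise ValueError("grouped split needs a 'drug' column")
        drugs = np.array(sorted(table["drug"].unique()))
        rng.shuffle(drugs)
        n_train_drugs = max(1, int(train_fraction * len(drugs)))
        train_set = set(drugs[:n_train_drugs])
        mask = table["drug"].isin(train_set).to_numpy()
        return table[mask], table[~mask]
    perm = rng.permutation(len(table))
    n_train = int(train_fraction * len(table))
    return table.iloc[perm[:n_train]], table.iloc[perm[n_train:]]


def evaluate(
    regressor,
    train: pd.DataFrame,
    test: pd.DataFrame,
    model_family: str = "tree_ensemble",
    split_seed: int = 0,
) -> EvalResult:
    """Fit on the training partition, score MAE/MSE/R2 on the held-out rows."""
    x_train = train[FEATURE_COLUMNS].to_numpy()
    y_train = train[TARGET_COLUMN].to_numpy()
    x_test = test[FEATURE_COLUMNS].to_numpy()
    y_test = test[TARGET_COLUMN].to_numpy()
    try:
        regressor.fit(x_train, y_train)
        pred = np.asarray(regressor.predict(x_test), float)
    except Exception as exc:
        raise RegressorError(model_family, exc) from exc
    return EvalResult(
        mae=float(mean_absolute_error(y_test, pred)),
        mse=float(mean_squared_error(y_test, pred)),
        r2=float(r2_score(y_test, pred)),
        model_family=model_family,
        split_seed=split_seed,
    )
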