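"""Fit-quality statistics and the optimizer toolbox.

The headline statistic is AARD% with a degrees-of-freedom denominator,

    AARD% = 100/(N - Z) * sum_i |pred_i - obs_i| / obs_i,

where Z is the number of fitted parameters; models of different arity are
thereby compared on a common footing. R_adj and the regression F-value use Q,
the number of independent regressors (intercept excluded).

Fitting of the density correlations runs in two stages: ordinary least
squares in the model's log-linear space (every registry model is log-linear)
seeds a multi-start Nelder-Mead polish of the requested objective, AARD by
default. A small seeded genetic algorithm and simulated annealer round out
the toolbox for non-log-linear problems (expanded-liquid-theory fits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .core_data import SolubilityDataset
from .density_models import (
    T_LN_Y2P,
    DensityModelSpec,
    FittedModel,
    get_spec,
)


class DegreesOfFreedomError(ValueError):
    """Too few observations for the number of fitted parameters."""


class FitFailureError(RuntimeError):
    """Optimizer failed on all starts; carries the best point seen."""

    def __init__(self, message: str, best_params=None, best_objective=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_objective = best_objective


@dataclass(frozen=True)
class FitStatistics:
    aard_pct: float
    r2: float
    r_adj: float
    f_value: float
    N: int
    Z: int
    Q: int
    f_infinite: bool = False


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings shared by the fitting routines; seed makes runs reproducible."""

    method: str = "nls"
    n_starts: int = 32
    seed: int = 20230809
    tolerance: float = 1e-10
    max_iter: int = 4000
    bounds: tuple[tuple[float, float], ...] | None = None
    # heuristic-optimizer knobs
    population: int = 64
    generations: int = 200
    mutation_sigma_frac: float = 0.05
    sa_steps: int = 10_000
    sa_cooling: float = 0.95

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


def aard(observed, predicted, Z: int) -> float:
    """AARD in percent with the N-Z degrees-of-freedom denominator."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have the same length")
    N = obs.size
    if N <= Z:
        raise DegreesOfFreedomError(f"need N > Z; got N={N}, Z={Z}")
    if np.any(obs == 0):
        raise ZeroDivisionError("observed values must be nonzero for relative deviations")
    return float(100.0 / (N - Z) * np.sum(np.abs(pred - obs) / np.abs(obs)))


def r_squared(observed, predicted) -> float:
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    ss_t = float(np.sum((obs - obs.mean()) ** 2))
    ss_e = float(np.sum((obs - pred) ** 2))
    if ss_t == 0:
        return 1.0 if ss_e == 0 else 0.0
    return 1.0 - ss_e / ss_t


def r_adjusted(observed, predicted, Q: int) -> float:
    """sqrt| R^2 - Q(1-R^2)/(N-Q-1) |, the adjusted correlation criterion."""
    obs = np.asarray(observed, float)
    N = obs.size
    if N <= Q + 1:
        raise DegreesOfFreedomError(f"need N > Q+1; got N={N}, Q={Q}")
    r2 = r_squared(observed, predicted)
    return math.sqrt(abs(r2 - Q * (1.0 - r2) / (N - Q - 1)))


def f_value(observed, predicted, Q: int) -> tuple[float, bool]:
    """Regression F statistic (MS_R/MS_E) about the observed mean.

    Returns (value, infinite_flag); a perfect fit has SS_E = 0 and is
    reported as infinite with the flag set.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    N = obs.size
    if N <= Q + 1:
        raise DegreesOfFreedomError(f"need N > Q+1; got N={N}, Q={Q}")
    ss_r = float(np.sum((pred - obs.mean()) ** 2))
    ss_e = float(np.sum((obs - pred) ** 2))
    if ss_e == 0:
        return math.inf, True
    return (ss_r / Q) / (ss_e / (N - Q - 1)), False


def compute_statistics(observed, predicted, Z: int, Q: int | None = None) -> FitStatistics:
    if Q is None:
        Q = max(Z - 1, 1)
    f, flag = f_value(observed, predicted, Q)
    return FitStatistics(
        aard_pct=aard(observed, predicted, Z),
        r2=r_squared(observed, predicted),
        r_adj=r_adjusted(observed, predicted, Q),
        f_value=f,
        N=len(np.asarray(observed)),
        Z=Z,
        Q=Q,
        f_infinite=flag,
    )


def _prediction_fn(spec: DensityModelSpec, dataset: SolubilityDataset) -> Callable:
    """Vectorized params -> predictions in the model's comparison space."""
    X = spec.design_matrix(dataset.column("T"), dataset.column("P"), dataset.column("rho"))
    T = dataset.column("T")
    P = dataset.column("P")

    def predict(params: np.ndarray) -> np.ndarray:
        g = X @ params
        if spec.output_space == T_LN_Y2P:
            # compare in mole-fraction space: invert T ln(y2 P)
            return np.exp(g / T) / P
        if spec.name == "bartle":
            return np.exp(g) * spec.constants["P_ref"] / P
        return np.exp(g)

    return predict


def _objective_fn(objective: str, obs: np.ndarray, predict: Callable, Z: int) -> Callable:
    N = obs.size
    log_obs = np.log(obs)

    def f(params: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            pred = predict(np.asarray(params, float))
        if not np.all(np.isfinite(pred)) or np.any(pred <= 0):
            return math.inf
        if objective == "aard":
            return float(100.0 / (N - Z) * np.sum(np.abs(pred - obs) / obs))
        if objective == "sse_linear":
            return float(np.sum((pred - obs) ** 2))
        if objective == "sse_log":
            return float(np.sum((np.log(pred) - log_obs) ** 2))
        raise ValueError(f"unknown objective {objective!r}")

    return f


def fit(
    model: DensityModelSpec | str,
    dataset: SolubilityDataset,
    objective: str = "aard",
    config: OptimizerConfig | None = None,
) -> FittedModel:
    """Fit one density correlation to a dataset.

    Least-squares in the model's log-linear space provides the first start;
    the remaining starts perturb it multiplicatively. Each start is polished
    by Nelder-Mead on the requested objective and the best result (lowest
    start index on ties) is returned with its fit statistics.
    """
    spec = get_spec(model) if isinstance(model, str) else model
    config = config or OptimizerConfig()
    N = len(dataset)
    Z = spec.n_params
    if N <= Z:
        raise DegreesOfFreedomError(f"{spec.name}: need more than {Z} points, got {N}")

    X = spec.design_matrix(dataset.column("T"), dataset.column("P"), dataset.column("rho"))
    target = spec.linear_target(dataset)
    ols, *_ = np.linalg.lstsq(X, target, rcond=None)

    obs = spec.comparison_observed(dataset)
    predict = _prediction_fn(spec, dataset)
    obj = _objective_fn(objective, obs, predict, Z)

    rng = np.random.default_rng(config.seed)
    best: tuple[float, np.ndarray] | None = None
    failures = 0
    for start_idx in range(config.n_starts):
        if start_idx == 0:
            x0 = ols.copy()
        else:
            scale = np.abs(ols) * 0.1 + 1e-3
            x0 = ols + rng.normal(0.0, scale)
        try:
            res = minimize(
                obj,
                x0,
                method="Nelder-Mead",
                options={
                    "xatol": 1e-12,
                    "fatol": config.tolerance,
                    "maxiter": config.max_iter,
                    "maxfev": config.max_iter,
                },
            )
        except Exception:
            failures += 1
            continue
        if not math.isfinite(res.fun):
            failures += 1
            continue
        if best is None or res.fun < best[0]:
            best = (float(res.fun), np.asarray(res.x, float))
    if best is None:
        raise FitFailureError(
            f"{spec.name}: all {config.n_starts} starts failed",
            best_params=tuple(ols),
            best_objective=obj(ols) if math.isfinite(obj(ols)) else None,
        )
    # restart the simplex at the winner until it stops improving: Nelder-Mead
    # often collapses prematurely on the piecewise-linear AARD surface
    for _ in range(3):
        res = minimize(
            obj,
            best[1],
            method="Nelder-Mead",
            options={
                "xatol": 1e-12,
                "fatol": config.tolerance,
                "maxiter": config.max_iter,
                "maxfev": config.max_iter,
            },
        )
        if math.isfinite(res.fun) and res.fun < best[0] - 1e-12:
            best = (float(res.fun), np.asarray(res.x, float))
        else:
            break
    params = tuple(float(p) for p in best[1])
    stats = compute_statistics(obs, predict(np.asarray(params)), Z)
    return FittedModel(spec=spec, params=params, stats=stats, dataset_label=dataset.label)


def _check_bounds(bounds) -> tuple[np.ndarray, np.ndarray]:
    if bounds is None or len(bounds) == 0:
        raise ValueError("finite bounds are required")
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(hi > lo)):
        raise ValueError("bounds must be finite with hi > lo")
    return lo, hi


def ga_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: OptimizerConfig | None = None,
) -> np.ndarray:
    """Seeded real-coded genetic algorithm.

    Tournament selection (size 3), blend crossover, Gaussian mutation with
    sigma a fixed fraction of the bound width, one elite per generation. The
    returned point is never worse than the best initial population member.
    """
    config = config or OptimizerConfig(method="ga")
    lo, hi = _check_bounds(bounds)
    width = hi - lo
    rng = np.random.default_rng(config.seed)
    pop = lo + rng.random((config.population, lo.size)) * width
    fitness = np.array([objective(ind) for ind in pop])
    best_i = int(np.argmin(fitness))
    best_x, best_f = pop[best_i].copy(), float(fitness[best_i])

    for _ in range(config.generations):
        new_pop = [best_x.copy()]  # elitism
        while len(new_pop) < config.population:
            # tournament selection of two parents
            parents = []
            for _k in range(2):
                idx = rng.integers(0, config.population, size=3)
                parents.append(pop[idx[np.argmin(fitness[idx])]])
            u = rng.random(lo.size)
            child = u * parents[0] + (1.0 - u) * parents[1]
            mutate = rng.random(lo.size) < 0.2
            child = child + mutate * rng.normal(0.0, config.mutation_sigma_frac * width)
            new_pop.append(np.clip(child, lo, hi))
        pop = np.array(new_pop)
        fitness = np.array([objective(ind) for ind in pop])
        i = int(np.argmin(fitness))
        if fitness[i] < best_f:
            best_x, best_f = pop[i].copy(), float(fitness[i])
    return best_x


def sa_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: OptimizerConfig | None = None,
) -> np.ndarray:
    """Seeded simulated annealing with geometric cooling.

    Gaussian proposals clipped to bounds; temperature multiplied by the
    cooling factor every 50 steps; returns the best point visited.
    """
    config = config or OptimizerConfig(method="sa")
    lo, hi = _check_bounds(bounds)
    width = hi - lo
    rng = np.random.default_rng(config.seed)
    x = lo + rng.random(lo.size) * width
    fx = objective(x)
    best_x, best_f = x.copy(), float(fx)
    temp = max(abs(fx), 1.0)
    for step in range(config.sa_steps):
        prop = np.clip(x + rng.normal(0.0, config.mutation_sigma_frac * width), lo, hi)
        fp = objective(prop)
        if fp < fx or rng.random() < math.exp(-(fp - fx) / max(temp, 1e-300)):
            x, fx = prop, fp
            if fx < best_f:
                best_x, best_f = x.copy(), float(fx)
        if (step + 1) % 50 == 0:
            temp *= config.sa_cooling
    return best_x
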