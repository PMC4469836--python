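"""Parameter search: grid sweeps with common random numbers and a small
real-coded genetic algorithm.

The sweep is the instrument behind the serotonin-sensitivity analyses
(which of ``alpha_d1``, ``alpha_d2``, ``alpha_d1d2`` actually drives each
behavior), and the GA reproduces the calibration workflow used to fit the
published parameter presets.  The GA option set here is deliberately
small and desk-scale (population 24, 40 generations, mutation 0.1,
crossover 0.7, tournament selection of 3 with elitism of 1); it makes no
claim to match any historical optimizer configuration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .neuromodulators import PDCondition, SerotoninParams
from .tasks import (
    EXPERIMENT_DEFAULTS,
    run_pd_experiment,
    run_reversal_experiment,
    run_risk_experiment,
)

__all__ = [
    "SearchSpec",
    "SweepResult",
    "FitResult",
    "experiment_simulator",
    "objective",
    "sweep",
    "fit",
]

Simulator = Callable[[Mapping[str, float], int], dict[str, float]]


@dataclass(frozen=True)
class SearchSpec:
    """Free parameters with bounds (or explicit grids), target statistics
    and a search budget.

    ``params`` maps a parameter name to ``(low, high)`` bounds for the GA
    or to an explicit sequence of grid values for ``method='grid'``.
    ``targets`` maps statistic names to ``(target, weight)``; the
    objective is the weighted sum of squared differences and is zero iff
    every target is matched exactly.
    """

    params: Mapping[str, Sequence[float] | tuple[float, float]]
    targets: Mapping[str, tuple[float, float]]
    method: str = "grid"
    budget: int = 1000
    ga_population: int = 24
    ga_generations: int = 40
    ga_mutation: float = 0.1
    ga_crossover: float = 0.7

    def __post_init__(self):
        if self.method not in ("grid", "ga"):
            raise ValueError(f"unknown search method: {self.method!r}")
        if self.budget <= 0:
            raise ValueError("search budget must be positive")
        for name, bounds in self.params.items():
            arr = np.asarray(bounds, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"bounds for {name!r} must be finite")


@dataclass
class SweepResult:
    """One row per evaluated grid point: the parameter vector, the
    simulated statistics (mean and SE columns) and the objective."""

    table: pd.DataFrame

    def best(self) -> pd.Series:
        return self.table.loc[self.table.objective.idxmin()]


@dataclass
class FitResult:
    best_params: dict[str, float]
    best_objective: float
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)


_ALPHA_KEYS = ("alpha_d1", "alpha_d2", "alpha_d1d2")
_PD_KEYS = ("delta_lim", "delta_med")


def experiment_simulator(
    experiment: str,
    *,
    n_agents: int = 50,
    base_alphas: SerotoninParams | None = None,
    base_pd: PDCondition | None = None,
    **fixed,
) -> Simulator:
    """Build a ``simulate(overrides, master_seed) -> statistics`` callable
    for one experiment condition.

    Override keys: the serotonin multipliers, ``delta_lim``/``delta_med``
    (PD experiment), and ``r_b`` (risk experiment).  Everything else uses
    the experiment's study defaults; the same master seed re-derives the
    same per-agent streams at every parameter vector, so re-evaluating a
    vector reproduces its statistics exactly.
    """
    if experiment not in EXPERIMENT_DEFAULTS:
        raise ValueError(f"unknown experiment: {experiment!r}")
    base_alphas = base_alphas or SerotoninParams()

    def simulate(overrides: Mapping[str, float], master_seed: int) -> dict[str, float]:
        alphas = {k: getattr(base_alphas, k) for k in _ALPHA_KEYS}
        alphas.update({k: float(v) for k, v in overrides.items() if k in _ALPHA_KEYS})
        sero = SerotoninParams(**alphas)
        if experiment == "risk":
            from .tasks import RiskSchedule

            r_b = float(overrides.get("r_b", 159.83))
            summary = run_risk_experiment(
                n_agents=n_agents,
                master_seed=master_seed,
                conditions={"point": sero},
                schedule=RiskSchedule.default(r_b=r_b),
                **fixed,
            )
        elif experiment == "reversal":
            summary = run_reversal_experiment(
                n_agents=n_agents,
                master_seed=master_seed,
                conditions={"point": sero},
                **fixed,
            )
        else:
            pd_base = base_pd or PDCondition()
            status = pd_base.status
            lim = float(overrides.get("delta_lim", pd_base.delta_lim))
            med = float(overrides.get("delta_med", pd_base.delta_med))
            summary = run_pd_experiment(
                n_agents=n_agents,
                master_seed=master_seed,
                conditions={"point": (sero, PDCondition(status, lim, med))},
                **fixed,
            )
        stats: dict[str, float] = {}
        for _, row in summary.summary.iterrows():
            stats[row["statistic"]] = float(row["mean"])
            stats[row["statistic"] + "_se"] = float(row["se"])
        return stats

    return simulate


def objective(stats: Mapping[str, float], targets: Mapping[str, tuple[float, float]]) -> float:
    """Weighted sum of squared differences between simulated and target
    statistics; invariant to target ordering."""
    total = 0.0
    for name, (target, weight) in targets.items():
        total += weight * (stats[name] - target) ** 2
    return float(total)


def _grid_points(params: Mapping[str, Sequence[float]]) -> list[dict[str, float]]:
    names = list(params)
    grids = [np.atleast_1d(np.asarray(params[n], dtype=float)) for n in names]
    return [dict(zip(names, combo)) for combo in itertools.product(*grids)]


def sweep(
    spec: SearchSpec,
    simulate: Simulator,
    master_seed: int = 0,
) -> SweepResult:
    """Evaluate every grid point with common random numbers and return the
    full table (one row per point)."""
    points = _grid_points(spec.params)[: spec.budget]
    rows = []
    for point in points:
        stats = simulate(point, master_seed)
        row = dict(point)
        row.update(stats)
        row["objective"] = objective(stats, spec.targets) if spec.targets else np.nan
        rows.append(row)
    return SweepResult(pd.DataFrame(rows))


def fit(
    spec: SearchSpec,
    simulate: Simulator,
    master_seed: int = 0,
) -> FitResult:
    """Minimize the target objective over the parameter bounds.

    ``method='grid'`` exhaustively evaluates the grid; ``method='ga'``
    runs the genetic algorithm (tournament selection 3, elitism 1,
    uniform crossover, per-gene Gaussian mutation scaled to 10% of the
    bound width).  The best-so-far objective trace is monotone
    non-increasing by construction.
    """
    if spec.method == "grid":
        result = sweep(spec, simulate, master_seed)
        best = result.best()
        params = {k: float(best[k]) for k in spec.params}
        return FitResult(params, float(best["objective"]), result.table)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(97,)))
    names = list(spec.params)
    lo = np.array([float(np.min(spec.params[n])) for n in names])
    hi = np.array([float(np.max(spec.params[n])) for n in names])
    span = hi - lo
    d = len(names)

    def evaluate(vec: np.ndarray) -> float:
        stats = simulate(dict(zip(names, vec)), master_seed)
        return objective(stats, spec.targets)

    pop_size = spec.ga_population
    pop = lo + rng.uniform(size=(pop_size, d)) * span
    fitness = np.array([evaluate(v) for v in pop])
    evals = pop_size
    trace_rows = []
    best_idx = int(np.argmin(fitness))
    best_vec, best_obj = pop[best_idx].copy(), float(fitness[best_idx])
    trace_rows.append((0, best_obj))

    for gen in range(1, spec.ga_generations + 1):
        if evals >= spec.budget:
            break
        children = [best_vec.copy()]  # elitism of 1
        while len(children) < pop_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(pop_size, size=3)
                parents.append(pop[contenders[np.argmin(fitness[contenders])]])
            p1, p2 = parents
            if rng.random() < spec.ga_crossover:
                mask = rng.random(d) < 0.5
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            mutate = rng.random(d) < spec.ga_mutation
            child = child + mutate * rng.normal(0.0, 0.1, d) * span
            children.append(np.clip(child, lo, hi))
        pop = np.array(children)
        fitness = np.array([evaluate(v) for v in pop])
        evals += pop_size
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_obj:
            best_obj = float(fitness[gen_best])
            best_vec = pop[gen_best].copy()
        trace_rows.append((gen, best_obj))

    trace = pd.DataFrame(trace_rows, columns=["generation", "best_objective"])
    return FitResult(dict(zip(names, best_vec)), best_obj, trace)
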