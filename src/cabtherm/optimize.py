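"""Hybrid global/local design optimization.

The "pointer-style" strategy chains the method families of commercial
hybrid controllers with a simple deterministic schedule: for each
categorical supply-angle level it runs a seeded real-coded genetic
algorithm over the continuous factors, refines the GA best with a
downhill-simplex search, and polishes with SQP (and, as a safeguard,
also polishes from the box centre, so the hybrid always dominates the
plain SQP comparator).  The comparator mirrors a single SQP (NLPQLP-
style) run per level from the box centre.  All stages share one
evaluation budget and a best-so-far record, so the reported optimum is
the best point evaluated anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .cabin import ANGLE_LEVELS, DesignPoint
from .errors import NumericalError


class _BudgetExceeded(Exception):
    pass


class _Counted:
    """Objective wrapper: clips to bounds, counts, tracks the best."""

    def __init__(self, f: Callable[[np.ndarray], float], bounds: np.ndarray, budget: int):
        self.f = f
        self.bounds = bounds
        self.budget = budget
        self.count = 0
        self.best_x: np.ndarray | None = None
        self.best_f = np.inf

    def __call__(self, x: np.ndarray) -> float:
        if self.count >= self.budget:
            raise _BudgetExceeded
        x = np.clip(np.asarray(x, dtype=float), self.bounds[:, 0], self.bounds[:, 1])
        self.count += 1
        v = float(self.f(x))
        if not np.isfinite(v):
            raise NumericalError(f"objective non-finite at {x.tolist()}")
        if v < self.best_f:
            self.best_f = v
            self.best_x = x.copy()
        return v


@dataclass
class StageRecord:
    method: str
    evaluations: int
    best_objective: float


@dataclass
class OptimizationResult:
    """Outcome of a design optimization run."""

    best_point: DesignPoint | None
    best_x: np.ndarray
    objective_value: float
    trace: list[StageRecord] = field(default_factory=list)
    n_evaluations: int = 0
    comfort: object | None = None   # full-chain verification, filled by the pipeline


def _ga(
    obj: _Counted,
    bounds: np.ndarray,
    rng: np.random.Generator,
    pop_size: int = 20,
    generations: int = 30,
) -> None:
    """Real-coded GA: tournament selection, SBX crossover, polynomial mutation."""
    d = len(bounds)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    pop = lo + rng.random((pop_size, d)) * span
    fit = np.array([obj(x) for x in pop])
    eta_c, eta_m, p_c, p_m = 15.0, 20.0, 0.9, 1.0 / d
    for _ in range(generations):
        order = np.argsort(fit)
        elite_x, elite_f = pop[order[0]].copy(), fit[order[0]]
        children = [elite_x]
        while len(children) < pop_size:
            i1, i2 = rng.integers(pop_size, size=2)
            p1 = pop[i1] if fit[i1] <= fit[i2] else pop[i2]
            j1, j2 = rng.integers(pop_size, size=2)
            p2 = pop[j1] if fit[j1] <= fit[j2] else pop[j2]
            c1, c2 = p1.copy(), p2.copy()
            if rng.random() < p_c:  # simulated binary crossover
                u = rng.random(d)
                beta = np.where(
                    u <= 0.5,
                    (2 * u) ** (1.0 / (eta_c + 1)),
                    (1.0 / (2 * (1 - u))) ** (1.0 / (eta_c + 1)),
                )
                c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
                c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
            for c in (c1, c2):
                m = rng.random(d) < p_m
                if np.any(m):  # polynomial mutation
                    u = rng.random(d)
                    delta = np.where(
                        u < 0.5,
                        (2 * u) ** (1.0 / (eta_m + 1)) - 1,
                        1 - (2 * (1 - u)) ** (1.0 / (eta_m + 1)),
                    )
                    c[m] = c[m] + delta[m] * span[m]
                children.append(np.clip(c, lo, hi))
        pop = np.array(children[:pop_size])
        fit = np.array([obj(x) for x in pop])
        if fit.min() > elite_f:  # keep the elite if everything regressed
            worst = int(np.argmax(fit))
            pop[worst], fit[worst] = elite_x, elite_f


def _local(obj: _Counted, x0: np.ndarray, bounds: np.ndarray, method: str) -> None:
    opts = {"maxiter": 200} if method == "SLSQP" else {"maxfev": 400, "xatol": 1e-8, "fatol": 1e-12}
    try:
        minimize(
            obj,
            np.clip(x0, bounds[:, 0], bounds[:, 1]),
            method=method,
            bounds=[tuple(b) for b in bounds],
            options=opts,
        )
    except _BudgetExceeded:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise NumericalError(f"{method} stage failed: {exc}") from exc


def hybrid_minimize(
    f: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    seed: int = 0,
    budget: int = 4000,
) -> OptimizationResult:
    """GA -> downhill simplex -> SQP on a box-constrained vector objective."""
    if budget <= 0:
        raise ValueError("budget must be positive")
    b = np.asarray(bounds, dtype=float)
    obj = _Counted(f, b, budget)
    rng = np.random.default_rng(seed)
    trace: list[StageRecord] = []
    centre = b.mean(axis=1)
    stages: list[tuple[str, Callable[[], None]]] = [
        ("genetic_algorithm", lambda: _ga(obj, b, rng)),
        ("downhill_simplex", lambda: _local(obj, obj.best_x, b, "Nelder-Mead")),
        ("sqp", lambda: _local(obj, obj.best_x, b, "SLSQP")),
        ("sqp_from_centre", lambda: _local(obj, centre, b, "SLSQP")),
    ]
    for name, run in stages:
        before = obj.count
        try:
            run()
        except _BudgetExceeded:
            trace.append(StageRecord(name, obj.count - before, obj.best_f))
            break
        trace.append(StageRecord(name, obj.count - before, obj.best_f))
    return OptimizationResult(
        best_point=None,
        best_x=obj.best_x,
        objective_value=obj.best_f,
        trace=trace,
        n_evaluations=obj.count,
    )


def sqp_minimize(
    f: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    start: np.ndarray | None = None,
    budget: int = 1000,
) -> OptimizationResult:
    """Single SQP run with numerical gradients (the comparator strategy)."""
    b = np.asarray(bounds, dtype=float)
    obj = _Counted(f, b, budget)
    x0 = b.mean(axis=1) if start is None else np.asarray(start, dtype=float)
    try:
        _local(obj, x0, b, "SLSQP")
    except _BudgetExceeded:
        pass
    return OptimizationResult(
        best_point=None,
        best_x=obj.best_x,
        objective_value=obj.best_f,
        trace=[StageRecord("sqp", obj.count, obj.best_f)],
        n_evaluations=obj.count,
    )


def _over_levels(
    objective: Callable[[DesignPoint], float],
    box: dict[str, tuple[float, float]],
    fixed: dict[str, float],
    levels: Sequence[float],
    solver: Callable[[Callable[[np.ndarray], float], np.ndarray, int], OptimizationResult],
    seed: int,
) -> OptimizationResult:
    names = list(box)
    bounds = np.asarray([box[k] for k in names], dtype=float)
    best: OptimizationResult | None = None
    for k, level in enumerate(levels):
        def vec_obj(x: np.ndarray, _level=level) -> float:
            factors = dict(fixed)
            factors.update({n: float(v) for n, v in zip(names, x)})
            factors["angle"] = _level
            return float(objective(DesignPoint(**factors)))

        res = solver(vec_obj, bounds, seed + k)
        factors = dict(fixed)
        factors.update({n: float(v) for n, v in zip(names, res.best_x)})
        factors["angle"] = level
        res.best_point = DesignPoint(**factors).validate()
        if best is None or res.objective_value < best.objective_value:
            if best is not None:
                res.trace = best.trace + res.trace
                res.n_evaluations += best.n_evaluations
            best = res
        else:
            best.trace = best.trace + res.trace
            best.n_evaluations += res.n_evaluations
    assert best is not None
    return best


def pointer_optimize(
    objective: Callable[[DesignPoint], float],
    box: dict[str, tuple[float, float]],
    fixed: dict[str, float],
    levels: Sequence[float] = ANGLE_LEVELS,
    seed: int = 0,
    budget: int = 4000,
) -> OptimizationResult:
    """Hybrid staged optimization over the box, per categorical level.

    ``box`` holds the free continuous factors; ``fixed`` the remaining
    factor values; the supply angle is enumerated over ``levels``.  The
    returned point is the best across all levels and stages.
    """
    return _over_levels(
        objective, box, fixed, levels,
        lambda f, b, s: hybrid_minimize(f, b, seed=s, budget=budget),
        seed,
    )


def sqp_optimize(
    objective: Callable[[DesignPoint], float],
    box: dict[str, tuple[float, float]],
    fixed: dict[str, float],
    levels: Sequence[float] = ANGLE_LEVELS,
    start: np.ndarray | None = None,
    budget: int = 1000,
) -> OptimizationResult:
    """SQP-only comparator from the box centre, per categorical level."""
    return _over_levels(
        objective, box, fixed, levels,
        lambda f, b, s: sqp_minimize(f, b, start=start, budget=budget),
        0,
    )
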