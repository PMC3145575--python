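"""Solving the compiled ILP and harvesting near-optimal solution pools.

The backend is HiGHS via :func:`scipy.optimize.milp`, which certifies
global optimality.  The pool is enumerated iteratively: solve, record the
topology, exclude it with a no-good cut on the presence variables, repeat
while the objective stays within the tolerance of the optimum and the pool
is below its cap.  Distinctness is therefore on topologies, not on state
assignments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .ilp import ILPProblem, ObjectiveWeights
from .io import ExperimentTable
from .network import ExtendedNetwork
from .simulate import BLOCK_ACTIVITY, simulate

__all__ = [
    "Solution",
    "SolutionPool",
    "SolverError",
    "solve",
    "enumerate_pool",
    "pool_cutoff",
    "edge_frequencies",
    "fit_error",
    "simulated_objective",
    "objective_from_presence",
    "exhaustive_search",
]

_BACKENDS = ("highs",)


class SolverError(RuntimeError):
    pass


@dataclass
class Solution:
    presence: dict[str, int]
    activations: dict[tuple[str, str], int]
    states: dict[tuple[str, str], int]
    objective_value: float

    def presence_vector(self, ids: list[str]) -> tuple[int, ...]:
        return tuple(self.presence[i] for i in ids)


@dataclass
class SolutionPool:
    solutions: list[Solution]
    tolerance: float
    optimum: float

    def __len__(self) -> int:
        return len(self.solutions)

    @property
    def objective_values(self) -> list[float]:
        return [s.objective_value for s in self.solutions]


def _check_backend(backend: str) -> None:
    if backend not in _BACKENDS:
        raise SolverError(
            f"unknown solver backend {backend!r}; available: {_BACKENDS}"
        )


def _run_milp(
    problem: ILPProblem,
    extra_rows=None,
    seed: int = 0,
    fixed: Mapping[str, int] | None = None,
):
    a = problem.a
    lb, ub = problem.con_lb, problem.con_ub
    if extra_rows:
        cut_a, cut_lb, cut_ub = extra_rows
        a = sp.vstack([a, cut_a], format="csr")
        lb = np.concatenate([lb, cut_lb])
        ub = np.concatenate([ub, cut_ub])
    var_lb, var_ub = problem.var_lb, problem.var_ub
    if fixed:
        var_lb = var_lb.copy()
        var_ub = var_ub.copy()
        for eid, val in fixed.items():
            col = problem.y_index[eid]
            var_lb[col] = var_ub[col] = val
    constraints = (
        LinearConstraint(a, lb, ub) if a.shape[0] else None
    )
    res = milp(
        c=problem.c,
        constraints=constraints,
        integrality=problem.integrality,
        bounds=Bounds(var_lb, var_ub),
        options={"mip_rel_gap": 0.0},
    )
    return res


def _decode(problem: ILPProblem, x: np.ndarray) -> Solution:
    rd = lambda col: int(round(x[col]))
    presence = {i: rd(col) for i, col in problem.y_index.items()}
    activations = {key: rd(col) for key, col in problem.z_index.items()}
    states = {key: rd(col) for key, col in problem.x_index.items()}
    obj = float(problem.c @ x + problem.offset)
    return Solution(
        presence=presence, activations=activations, states=states, objective_value=obj
    )


def solve(
    problem: ILPProblem,
    backend: str = "highs",
    seed: int = 0,
    fixed: Mapping[str, int] | None = None,
) -> Solution:
    """Solve to guaranteed global optimality.

    ``fixed`` optionally pins presence variables (edge id -> {0, 1}), used
    e.g. to test whether an edge is forced in or out of the near-optimal
    set.  The returned objective is checked against an independent
    recomputation from the presence vector (forward simulation); a
    discrepancy beyond 1e-6 raises, since it would mean the compiled
    constraints and the Boolean semantics disagree.
    """
    _check_backend(backend)
    res = _run_milp(problem, seed=seed, fixed=fixed)
    if not res.success:
        raise SolverError(f"solver failed: {res.message}")
    sol = _decode(problem, res.x)
    check = objective_from_presence(problem, sol.presence)
    if abs(check - sol.objective_value) > 1e-6 * max(1.0, abs(check)):
        raise SolverError(
            f"objective mismatch: ILP {sol.objective_value} vs simulated {check}"
        )
    return sol


def pool_cutoff(optimum: float, tolerance: float, beta_size: float) -> float:
    """Objective cutoff of the near-optimal pool: relative tolerance around
    a positive optimum, absolute tolerance of one map-size unit at 0."""
    if optimum > 1e-9:
        return optimum * (1.0 + tolerance)
    return optimum + beta_size


def _no_good_cut(problem: ILPProblem, presence: Mapping[str, int]):
    cols, vals = [], []
    ones = 0
    for i, col in problem.y_index.items():
        if presence[i] == 1:
            cols.append(col)
            vals.append(-1.0)
            ones += 1
        else:
            cols.append(col)
            vals.append(1.0)
    row = sp.coo_matrix(
        (vals, (np.zeros(len(cols), dtype=int), cols)), shape=(1, problem.n_vars)
    ).tocsr()
    return row, np.array([1.0 - ones]), np.array([np.inf])


def enumerate_pool(
    problem: ILPProblem,
    tolerance: float = 0.10,
    max_solutions: int = 100,
    backend: str = "highs",
    seed: int = 0,
) -> SolutionPool:
    """Harvest up to ``max_solutions`` distinct near-optimal topologies.

    Solutions are admitted while objective <= optimum * (1 + tolerance);
    for a zero optimum the cutoff is optimum + beta_size (relative
    tolerance is undefined at 0).  Returned in discovery order; when fewer
    near-optimal topologies exist than the cap, the pool is complete.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    _check_backend(backend)
    first = solve(problem, backend=backend, seed=seed)
    optimum = first.objective_value
    cutoff = pool_cutoff(optimum, tolerance, problem.weights.beta_size)
    cutoff += 1e-9 + 1e-7 * max(1.0, abs(optimum))

    solutions = [first]
    cut_a, cut_lb, cut_ub = _no_good_cut(problem, first.presence)
    while len(solutions) < max_solutions:
        res = _run_milp(problem, extra_rows=(cut_a, cut_lb, cut_ub), seed=seed)
        if not res.success:  # all topologies excluded
            break
        sol = _decode(problem, res.x)
        if sol.objective_value > cutoff:
            break
        solutions.append(sol)
        row, lo, hi = _no_good_cut(problem, sol.presence)
        cut_a = sp.vstack([cut_a, row], format="csr")
        cut_lb = np.concatenate([cut_lb, lo])
        cut_ub = np.concatenate([cut_ub, hi])
    return SolutionPool(solutions=solutions, tolerance=tolerance, optimum=optimum)


def edge_frequencies(pool: SolutionPool) -> dict[str, float]:
    """Fraction of pool solutions containing each reaction/edge."""
    if not pool.solutions:
        raise ValueError("empty solution pool")
    counts: dict[str, int] = {}
    for sol in pool.solutions:
        for eid, present in sol.presence.items():
            counts[eid] = counts.get(eid, 0) + int(present)
    return {eid: c / len(pool.solutions) for eid, c in counts.items()}


# ---------------------------------------------------------------------------
# Fit error and the simulation-based objective (independent of the ILP path)


def _measured_entries(
    net: ExtendedNetwork,
    data: ExperimentTable,
    presence: Mapping[str, int],
    inhibitor_mode: str,
    skip_responses: set[str] | None = None,
):
    """Yield (predicted, measured) for every measured entry."""
    skip = skip_responses or set()
    for cond in data.conditions:
        assignment = simulate(net, presence, cond, inhibitor_mode=inhibitor_mode)
        for sig in data.signals.columns:
            v = data.signals.loc[cond.id, sig]
            if not np.isnan(v):
                yield float(assignment.states[sig]), float(v)
        for resp in data.responses.columns:
            if resp in skip:
                continue
            v = data.responses.loc[cond.id, resp]
            if not np.isnan(v):
                yield float(assignment.response_values.get(resp, 0.0)), float(v)


def fit_error(
    net: ExtendedNetwork,
    presence: Mapping[str, int],
    data: ExperimentTable,
    inhibitor_mode: str = BLOCK_ACTIVITY,
) -> float:
    """Mean absolute deviation between simulated and measured values over
    all measured signal and response entries, in percent."""
    devs = [
        abs(p - m)
        for p, m in _measured_entries(net, data, presence, inhibitor_mode)
    ]
    if not devs:
        raise ValueError("no measured entries")
    return 100.0 * float(np.mean(devs))


def _degenerate_responses(net: ExtendedNetwork) -> set[str]:
    """Responses with incoming edges but a zero-width yield range (these
    are dropped from the ILP objective, so drop them here too)."""
    from .simulate import yield_bounds_of

    out = set()
    for resp in net.responses:
        edges = net.edges_into(resp)
        if edges:
            lo, hi = yield_bounds_of(edges)
            if hi - lo <= 0:
                out.add(resp)
    return out


def simulated_objective(
    net: ExtendedNetwork,
    data: ExperimentTable,
    presence: Mapping[str, int],
    weights: ObjectiveWeights = ObjectiveWeights(),
    inhibitor_mode: str = BLOCK_ACTIVITY,
    skip_responses: set[str] | None = None,
) -> float:
    """Three-term objective of a presence vector, computed by forward
    simulation (no ILP involved)."""
    skip = _degenerate_responses(net) if skip_responses is None else skip_responses
    mismatch_s = 0.0
    mismatch_r = 0.0
    for cond in data.conditions:
        assignment = simulate(net, presence, cond, inhibitor_mode=inhibitor_mode)
        for sig in data.signals.columns:
            v = data.signals.loc[cond.id, sig]
            if not np.isnan(v):
                mismatch_s += abs(assignment.states[sig] - float(v))
        for resp in data.responses.columns:
            if resp in skip:
                continue
            v = data.responses.loc[cond.id, resp]
            if not np.isnan(v):
                pred = assignment.response_values.get(resp, 0.0)
                mismatch_r += abs(pred - float(v))
    ids = [r.id for r in net.reactions] + [e.id for e in net.response_edges]
    size = sum(presence[i] for i in ids)
    return (
        weights.alpha_signal * mismatch_s
        + weights.alpha_response * mismatch_r
        + weights.beta_size * size
    )


def objective_from_presence(problem: ILPProblem, presence: Mapping[str, int]) -> float:
    return simulated_objective(
        problem.net,
        problem.data,
        presence,
        problem.weights,
        problem.inhibitor_mode,
        skip_responses=set(problem.dropped_responses),
    )


def exhaustive_search(
    net: ExtendedNetwork,
    data: ExperimentTable,
    weights: ObjectiveWeights = ObjectiveWeights(),
    inhibitor_mode: str = BLOCK_ACTIVITY,
) -> tuple[float, dict[str, int]]:
    """Brute-force optimum over all 2^R presence vectors, with states
    obtained by forward simulation.  Exponential: only for small networks.
    """
    ids = [r.id for r in net.reactions] + [e.id for e in net.response_edges]
    if len(ids) > 22:
        raise ValueError("exhaustive search limited to <= 22 presence variables")
    best, best_vec = np.inf, None
    for bits in itertools.product((0, 1), repeat=len(ids)):
        presence = dict(zip(ids, bits))
        obj = simulated_objective(
            net, data, presence, weights, inhibitor_mode=inhibitor_mode
        )
        if obj < best - 1e-12:
            best, best_vec = obj, presence
    return float(best), best_vec
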