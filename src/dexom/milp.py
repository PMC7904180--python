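"""Minimal mixed-integer linear programming layer.

Problems are stored as sparse rows and solved through a named backend; the
default (and currently only) backend is HiGHS via :func:`scipy.optimize.milp`.
The container supports the incremental edits the enumeration strategies need:
appending constraint rows (integer cuts), swapping the objective, and
temporarily changing variable bounds.
"""

from __future__ import annotations

import contextlib
import os
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = ["LinearProblem", "MilpResult", "SolverConfig", "solve", "write_lp", "SOLVERS"]

_INF = np.inf


@dataclass
class SolverConfig:
    """Solver-side knobs.

    ``mip_gap`` is the relative optimality gap accepted by the solver (0 means
    prove optimality); ``integer_feasibility_tol`` is used when rounding binary
    values out of the solution vector.  ``seed`` is recorded for provenance;
    the HiGHS runs used here are deterministic.
    """

    solver_name: str = "highs"
    per_solve_timeout: float = 300.0
    mip_gap: float = 0.0
    integer_feasibility_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_solve_timeout <= 0:
            raise ValueError("per_solve_timeout must be > 0")
        if not 0 <= self.mip_gap < 1:
            raise ValueError("mip_gap must be in [0, 1)")


class LinearProblem:
    """A (MI)LP: variables with bounds/integrality, sparse rows, one objective."""

    def __init__(self) -> None:
        self.var_names: list[str] = []
        self.var_lb: list[float] = []
        self.var_ub: list[float] = []
        self.var_integer: list[bool] = []
        # each row: (coefs {var_idx: coef}, row_lb, row_ub)
        self.rows: list[tuple[dict[int, float], float, float]] = []
        self.objective: dict[int, float] = {}
        self.maximize: bool = True

    # -- construction -------------------------------------------------------
    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    def add_var(
        self, name: str, lb: float = 0.0, ub: float = _INF, integer: bool = False
    ) -> int:
        self.var_names.append(name)
        self.var_lb.append(lb)
        self.var_ub.append(ub)
        self.var_integer.append(integer)
        return len(self.var_names) - 1

    def add_row(
        self, coefs: Mapping[int, float], lb: float = -_INF, ub: float = _INF
    ) -> int:
        self.rows.append((dict(coefs), lb, ub))
        return len(self.rows) - 1

    def set_row_bounds(self, row: int, lb: float, ub: float) -> None:
        coefs, _, _ = self.rows[row]
        self.rows[row] = (coefs, lb, ub)

    def set_var_bounds(self, idx: int, lb: float, ub: float) -> None:
        self.var_lb[idx] = lb
        self.var_ub[idx] = ub

    def get_var_bounds(self, idx: int) -> tuple[float, float]:
        return self.var_lb[idx], self.var_ub[idx]

    def set_objective(self, coefs: Mapping[int, float], maximize: bool = True) -> None:
        self.objective = dict(coefs)
        self.maximize = maximize

    def pop_rows(self, down_to: int) -> None:
        """Drop constraint rows with index >= *down_to*."""
        del self.rows[down_to:]

    # -- assembly -----------------------------------------------------------
    def constraint_matrix(self) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
        data, ri, ci = [], [], []
        lbs = np.empty(len(self.rows))
        ubs = np.empty(len(self.rows))
        for k, (coefs, lb, ub) in enumerate(self.rows):
            lbs[k], ubs[k] = lb, ub
            for j, c in coefs.items():
                ri.append(k)
                ci.append(j)
                data.append(c)
        A = sp.csr_matrix(
            (data, (ri, ci)), shape=(len(self.rows), self.n_vars)
        )
        return A, lbs, ubs

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(self.n_vars)
        for j, v in self.objective.items():
            c[j] = v
        return c


@dataclass
class MilpResult:
    status: str  # optimal | feasible | infeasible | timeout | unbounded | error
    x: np.ndarray | None
    objective: float | None
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status in ("optimal", "feasible")


@contextlib.contextmanager
def _quiet_stdout():
    # this HiGHS build prints C-level diagnostics to fd 1 even with disp off
    try:
        saved = os.dup(1)
    except OSError:
        yield
        return
    devnull = os.open(os.devnull, os.O_WRONLY)
    try:
        os.dup2(devnull, 1)
        yield
    finally:
        os.dup2(saved, 1)
        os.close(saved)
        os.close(devnull)


def _solve_highs(problem: LinearProblem, config: SolverConfig) -> MilpResult:
    c = problem.objective_vector()
    sign = -1.0 if problem.maximize else 1.0
    A, lbs, ubs = problem.constraint_matrix()
    constraints = LinearConstraint(A, lbs, ubs) if A.shape[0] else ()
    options = {"time_limit": float(config.per_solve_timeout)}
    if config.mip_gap > 0:
        options["mip_rel_gap"] = config.mip_gap
    with _quiet_stdout():
        res = milp(
            c=sign * c,
            integrality=np.array(problem.var_integer, dtype=int),
            bounds=Bounds(np.array(problem.var_lb), np.array(problem.var_ub)),
            constraints=constraints,
            options=options,
        )
    if res.status == 0:
        return MilpResult("optimal", res.x, float(c @ res.x), res.message)
    if res.status == 1:  # iteration/time limit; may carry an incumbent
        if res.x is not None:
            return MilpResult("timeout", res.x, float(c @ res.x), res.message)
        return MilpResult("timeout", None, None, res.message)
    if res.status == 2:
        return MilpResult("infeasible", None, None, res.message)
    if res.status == 3:
        return MilpResult("unbounded", None, None, res.message)
    return MilpResult("error", None, None, res.message)


SOLVERS: dict[str, Callable[[LinearProblem, SolverConfig], MilpResult]] = {
    "highs": _solve_highs,
}


def solve(problem: LinearProblem, config: SolverConfig | None = None) -> MilpResult:
    config = config or SolverConfig()
    try:
        backend = SOLVERS[config.solver_name]
    except KeyError:
        raise ValueError(
            f"unknown solver {config.solver_name!r}; available: {sorted(SOLVERS)}"
        ) from None
    return backend(problem, config)


def write_lp(problem: LinearProblem, path) -> None:
    """Export the problem in CPLEX LP format (for debugging)."""

    def term(coef: float, name: str) -> str:
        return f"{'+' if coef >= 0 else '-'} {abs(coef):g} {name} "

    lines = ["Maximize" if problem.maximize else "Minimize", " obj: "]
    obj = "".join(
        term(c, problem.var_names[j]) for j, c in sorted(problem.objective.items())
    )
    lines[1] += obj or "0 " + problem.var_names[0] if problem.var_names else "0"
    lines.append("Subject To")
    for k, (coefs, lb, ub) in enumerate(problem.rows):
        expr = "".join(term(c, problem.var_names[j]) for j, c in sorted(coefs.items()))
        if lb == ub:
            lines.append(f" c{k}: {expr}= {lb:g}")
        else:
            if ub < _INF:
                lines.append(f" c{k}u: {expr}<= {ub:g}")
            if lb > -_INF:
                lines.append(f" c{k}l: {expr}>= {lb:g}")
    lines.append("Bounds")
    for j, name in enumerate(problem.var_names):
        lines.append(f" {problem.var_lb[j]:g} <= {name} <= {problem.var_ub[j]:g}")
    binaries = [n for n, isint in zip(problem.var_names, problem.var_integer) if isint]
    if binaries:
        lines.append("Binaries")
        lines.append(" " + " ".join(binaries))
    lines.append("End")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
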