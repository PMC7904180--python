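"""The iMAT MILP: maximal agreement between reaction activity and expression.

Given a partition of reactions into R_H (associated with highly expressed
enzymes) and R_L (lowly expressed), iMAT selects a steady-state flux
distribution maximizing the number of R_H reactions carrying at least ε flux
plus the number of R_L reactions carrying none:

    max  Σ_{i∈R_H} (x⁺_i + x⁻_i)  +  Σ_{i∈R_L} xᵒ_i
    s.t. S·v = 0,  v_min ≤ v ≤ v_max
         v_i + x⁺_i (v_min,i − ε) ≥ v_min,i     i ∈ R_H   (x⁺=1 ⇒ v ≥ ε)
         v_i + x⁻_i (v_max,i + ε) ≤ v_max,i     i ∈ R_H   (x⁻=1 ⇒ v ≤ −ε)
         v_i + xᵒ_i v_min,i ≥ v_min,i           i ∈ R_L   (xᵒ=1 ⇒ v ≥ 0)
         v_i + xᵒ_i v_max,i ≤ v_max,i           i ∈ R_L   (xᵒ=1 ⇒ v ≤ 0)

x⁻ exists only for reversible R_H reactions (x⁺ + x⁻ ≤ 1).  ε is the minimal
flux magnitude for a reaction to count as active.

For enumeration the problem is augmented with one consolidated binary activity
indicator a_i per reaction (see :func:`add_activity_indicators`); integer cuts,
the optimality equality and the max-dissimilarity objective are all expressed
over those indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DimensionError
from .milp import LinearProblem, MilpResult, SolverConfig, solve
from .model import MetabolicModel, ReactionPartition

__all__ = [
    "ImatProblem",
    "ImatSolution",
    "SolverConfig",
    "build_imat",
    "add_activity_indicators",
    "add_optimality_constraint",
    "score",
    "solve_imat",
]

DEFAULT_EPSILON = 1e-3
FLUX_ZERO_TOL = 1e-6  # |v| below this is treated as no flux
FLUX_SNAP_TOL = 1e-9  # solver round-off snapped to exactly 0


@dataclass
class ImatProblem:
    """An iMAT MILP plus the bookkeeping the enumeration layer needs."""

    model: MetabolicModel
    partition: ReactionPartition
    epsilon: float
    lp: LinearProblem
    v_idx: np.ndarray  # flux variable index per reaction
    xplus: dict[int, int] = field(default_factory=dict)  # reaction idx -> var idx
    xminus: dict[int, int] = field(default_factory=dict)
    xo: dict[int, int] = field(default_factory=dict)
    act_idx: dict[int, int] | None = None  # consolidated activity indicators
    n_structural_rows: int = 0  # rows belonging to the base formulation
    optimality_row: int | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def objective_binaries(self) -> list[int]:
        """Variable indices of the Eq-style objective binaries (x⁺, x⁻, xᵒ)."""
        return (
            list(self.xplus.values())
            + list(self.xminus.values())
            + list(self.xo.values())
        )

    def rh_indices(self) -> list[int]:
        ids = self.model.reaction_ids
        return [i for i, rid in enumerate(ids) if rid in self.partition.rh]

    def rl_indices(self) -> list[int]:
        ids = self.model.reaction_ids
        return [i for i, rid in enumerate(ids) if rid in self.partition.rl]


@dataclass
class ImatSolution:
    """One optimal (or incumbent) context-specific network."""

    flux: np.ndarray | None
    activity: np.ndarray | None  # 0/1 per reaction, direction-insensitive
    score: int | None
    status: str  # optimal | feasible | infeasible | timeout
    objective: float | None = None

    @property
    def fingerprint(self) -> bytes | None:
        if self.activity is None:
            return None
        return np.asarray(self.activity, dtype=np.uint8).tobytes()


def build_imat(
    model: MetabolicModel,
    partition: ReactionPartition,
    epsilon: float = DEFAULT_EPSILON,
) -> ImatProblem:
    """Assemble the iMAT MILP for *model* under *partition*."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    partition.validate_for(model)

    lp = LinearProblem()
    n = model.n_reactions
    lb = model.lower_bounds()
    ub = model.upper_bounds()
    v_idx = np.array(
        [lp.add_var(f"v_{r.id}", lb[i], ub[i]) for i, r in enumerate(model.reactions)]
    )

    # steady state S·v = 0
    S = model.stoichiometric_matrix
    for row in range(S.shape[0]):
        coefs = {int(v_idx[j]): float(S[row, j]) for j in np.nonzero(S[row])[0]}
        if coefs:
            lp.add_row(coefs, 0.0, 0.0)

    prob = ImatProblem(model, partition, epsilon, lp, v_idx)

    rh = partition.rh
    rl = partition.rl
    for i, rxn in enumerate(model.reactions):
        vi = int(v_idx[i])
        if rxn.id in rh:
            if ub[i] < epsilon and lb[i] > -epsilon:
                prob.warnings.append(
                    f"R_H reaction {rxn.id!r} can never reach |v| >= {epsilon}"
                )
            xp = lp.add_var(f"xp_{rxn.id}", 0, 1, integer=True)
            prob.xplus[i] = xp
            # v + x⁺(v_min − ε) ≥ v_min
            lp.add_row({vi: 1.0, xp: lb[i] - epsilon}, lb[i], np.inf)
            if lb[i] < 0:  # reversible (or reverse-capable): backward activation
                xm = lp.add_var(f"xm_{rxn.id}", 0, 1, integer=True)
                prob.xminus[i] = xm
                # v + x⁻(v_max + ε) ≤ v_max
                lp.add_row({vi: 1.0, xm: ub[i] + epsilon}, -np.inf, ub[i])
                lp.add_row({xp: 1.0, xm: 1.0}, -np.inf, 1.0)
        elif rxn.id in rl:
            xo = lp.add_var(f"xo_{rxn.id}", 0, 1, integer=True)
            prob.xo[i] = xo
            # xᵒ=1 ⇒ v = 0
            lp.add_row({vi: 1.0, xo: lb[i]}, lb[i], np.inf)
            lp.add_row({vi: 1.0, xo: ub[i]}, -np.inf, ub[i])

    lp.set_objective({j: 1.0 for j in prob.objective_binaries}, maximize=True)
    prob.n_structural_rows = len(lp.rows)
    return prob


def add_activity_indicators(problem: ImatProblem) -> ImatProblem:
    """Add one consolidated binary activity indicator a_i per reaction.

    a_i = 1 ⟺ reaction i carries |v_i| ≥ ε; a_i = 0 ⟺ v_i = 0.  For R_H
    reactions a_i is tied to x⁺ + x⁻; for R_L reactions xᵒ is tied to 1 − a_i.
    Reactions outside the partition get their own directional indicators.
    Fluxes strictly between 0 and ε are thereby excluded for every reaction:
    enumeration operates on ε-quantized networks, which makes the activity
    vector a well-defined function of the MILP solution.
    """
    if problem.act_idx is not None:
        return problem
    lp = problem.lp
    eps = problem.epsilon
    lb = problem.model.lower_bounds()
    ub = problem.model.upper_bounds()
    act: dict[int, int] = {}
    for i, rxn in enumerate(problem.model.reactions):
        vi = int(problem.v_idx[i])
        if i in problem.xplus:
            # a = x⁺ (+ x⁻); Eq-style constraints already force |v| ≥ ε when set,
            # and we additionally force v = 0 when a = 0.
            a = lp.add_var(f"a_{rxn.id}", 0, 1, integer=True)
            coefs = {a: 1.0, problem.xplus[i]: -1.0}
            if i in problem.xminus:
                coefs[problem.xminus[i]] = -1.0
            lp.add_row(coefs, 0.0, 0.0)
            _add_activation_rows(lp, vi, a_fwd=problem.xplus.get(i),
                                 a_bwd=problem.xminus.get(i),
                                 lb=lb[i], ub=ub[i], eps=eps, link=False)
        else:
            fwd = ub[i] > 0
            bwd = lb[i] < 0
            if fwd and bwd:
                ap = lp.add_var(f"ap_{rxn.id}", 0, 1, integer=True)
                am = lp.add_var(f"am_{rxn.id}", 0, 1, integer=True)
                a = lp.add_var(f"a_{rxn.id}", 0, 1, integer=True)
                lp.add_row({a: 1.0, ap: -1.0, am: -1.0}, 0.0, 0.0)
                lp.add_row({ap: 1.0, am: 1.0}, -np.inf, 1.0)
                # v ≥ ε·a⁺ + v_min·a⁻ ; v ≤ v_max·a⁺ − ε·a⁻
                lp.add_row({vi: 1.0, ap: -eps, am: -lb[i]}, 0.0, np.inf)
                lp.add_row({vi: 1.0, ap: -ub[i], am: eps}, -np.inf, 0.0)
            elif fwd:
                a = lp.add_var(f"a_{rxn.id}", 0, 1, integer=True)
                lp.add_row({vi: 1.0, a: -eps}, 0.0, np.inf)  # a=1 ⇒ v ≥ ε
                lp.add_row({vi: 1.0, a: -ub[i]}, -np.inf, 0.0)  # a=0 ⇒ v ≤ 0
            elif bwd:
                a = lp.add_var(f"a_{rxn.id}", 0, 1, integer=True)
                lp.add_row({vi: 1.0, a: eps}, -np.inf, 0.0)  # a=1 ⇒ v ≤ −ε
                lp.add_row({vi: 1.0, a: -lb[i]}, 0.0, np.inf)  # a=0 ⇒ v ≥ 0
            else:  # blocked reaction: permanently inactive
                a = lp.add_var(f"a_{rxn.id}", 0, 0, integer=True)
            if i in problem.xo:
                lp.add_row({a: 1.0, problem.xo[i]: 1.0}, 1.0, 1.0)  # xᵒ = 1 − a
        act[i] = a
    problem.act_idx = act
    problem.n_structural_rows = len(lp.rows)
    return problem


def _add_activation_rows(lp, vi, a_fwd, a_bwd, lb, ub, eps, link):
    # For R_H reactions: force v = 0 when neither direction indicator is set.
    coefs_hi = {vi: 1.0}
    coefs_lo = {vi: 1.0}
    if a_fwd is not None:
        coefs_hi[a_fwd] = -ub
        coefs_lo[a_fwd] = coefs_lo.get(a_fwd, 0.0) - eps
    if a_bwd is not None:
        coefs_lo[a_bwd] = coefs_lo.get(a_bwd, 0.0) - lb
        coefs_hi[a_bwd] = coefs_hi.get(a_bwd, 0.0) + eps
    lp.add_row(coefs_lo, 0.0, np.inf)
    lp.add_row(coefs_hi, -np.inf, 0.0)


def score(activity: Sequence[int], partition: ReactionPartition,
          model: MetabolicModel) -> int:
    """Agreement score of an activity vector with the R_H/R_L partition."""
    activity = np.asarray(activity)
    if activity.shape != (model.n_reactions,):
        raise DimensionError(
            f"activity length {activity.shape} != {model.n_reactions} reactions"
        )
    ids = model.reaction_ids
    s = 0
    for i, rid in enumerate(ids):
        if rid in partition.rh:
            s += int(activity[i] == 1)
        elif rid in partition.rl:
            s += int(activity[i] == 0)
    return s


def add_optimality_constraint(problem: ImatProblem, z_star: int) -> ImatProblem:
    """Pin the iMAT objective to its optimum: Σ x = z*.

    Every solution feasible afterwards is optimal for the original objective.
    """
    coefs = {j: 1.0 for j in problem.objective_binaries}
    if problem.optimality_row is not None:
        problem.lp.set_row_bounds(problem.optimality_row, float(z_star), float(z_star))
    else:
        problem.optimality_row = problem.lp.add_row(coefs, float(z_star), float(z_star))
        problem.n_structural_rows = max(
            problem.n_structural_rows, len(problem.lp.rows)
        )
    return problem


def derive_activity(problem: ImatProblem, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Consolidate a raw solver vector into (flux, 0/1 activity).

    With the indicator layer installed the activity is read off the a_i
    binaries; otherwise it is derived from fluxes: R_H reactions are active at
    |v| ≥ ε(1 − 1e-6), any other reaction at |v| > 1e-6.  Fluxes below the snap
    tolerance are zeroed first to guard against solver round-off.
    """
    flux = x[problem.v_idx].copy()
    flux[np.abs(flux) < FLUX_SNAP_TOL] = 0.0
    n = problem.model.n_reactions
    activity = np.zeros(n, dtype=np.int8)
    if problem.act_idx is not None:
        for i, a in problem.act_idx.items():
            activity[i] = int(round(x[a]))
        leak = (activity == 0) & (np.abs(flux) > problem.epsilon / 2)
        if leak.any():
            warnings.warn(
                "reactions marked inactive carry flux near the activation "
                "threshold; epsilon is too close to (bound x solver integer "
                f"tolerance) for this model: {np.nonzero(leak)[0][:5]}"
            )
    else:
        eps_eff = problem.epsilon * (1 - 1e-6)
        rh_idx = set(problem.rh_indices())
        for i in range(n):
            if i in rh_idx:
                activity[i] = int(abs(flux[i]) >= eps_eff)
            else:
                activity[i] = int(abs(flux[i]) > FLUX_ZERO_TOL)
    return flux, activity


def solve_imat(
    problem: ImatProblem, config: SolverConfig | None = None
) -> ImatSolution:
    """Solve the (possibly augmented) iMAT MILP and package the solution."""
    res: MilpResult = solve(problem.lp, config)
    if res.x is None:
        status = res.status if res.status in ("infeasible", "timeout") else "infeasible"
        return ImatSolution(None, None, None, status)
    flux, activity = derive_activity(problem, res.x)
    sol_score = score(activity, problem.partition, problem.model)
    status = res.status if res.status in ("optimal", "timeout") else "feasible"
    return ImatSolution(flux, activity, sol_score, status, objective=res.objective)
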