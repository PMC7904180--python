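"""Enumeration of alternate optimal context-specific networks.

Four strategies, all producing deduplicated sets of optimal activity vectors
sharing the iMAT optimum z*:

* ``reaction_enum`` — flip each reaction's state relative to a reference
  optimum (block it if active, force flux if inactive) and keep perturbed
  solutions that are still optimal.
* ``icut_enum`` — exhaustive enumeration: after each solution an integer cut
  excludes it, until the MILP becomes infeasible (then the set is the complete
  Ω*).
* ``maxdist_enum`` — repeatedly find the solution with minimal overlap of
  active reactions with the previous one (= maximal Hamming distance at fixed
  score), with integer cuts preventing revisits.
* ``diversity_enum`` — seed with reaction_enum, then progressively transition
  from near to maximally distant solutions: at step i each active reaction of
  the current solution enters the dissimilarity target independently with
  probability 1 − d_s^i.

Cuts, the optimality equality and the dissimilarity objective are expressed
over consolidated per-reaction activity indicators, so solution identity is
"same set of active reactions", direction-insensitive.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, InfeasibleProblemError
from .imat import (
    ImatProblem,
    ImatSolution,
    SolverConfig,
    add_activity_indicators,
    add_optimality_constraint,
    build_imat,
    solve_imat,
)
from .model import MetabolicModel, ReactionPartition

__all__ = [
    "EnumerationConfig",
    "SolutionSet",
    "IntegerCut",
    "make_integer_cut",
    "pick_probability",
    "reaction_enum",
    "icut_enum",
    "maxdist_enum",
    "diversity_enum",
    "save_solution_set",
    "load_solution_set",
]


@dataclass
class EnumerationConfig:
    method: str = "icut"  # reaction | icut | maxdist | diversity
    max_solutions: int = 1000
    max_wall_time: float | None = None  # seconds; None = unlimited
    d_s: float = 0.995  # diversity-enum distance schedule parameter
    seed: int = 0
    track_states: bool = True  # reaction-enum duplicate-skipping option
    epsilon: float = 1e-3
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if self.max_solutions < 1:
            raise ValueError("max_solutions must be >= 1")
        if not 0 <= self.d_s <= 1:
            raise ValueError("d_s must be in [0, 1]")


class SolutionSet:
    """Ordered, fingerprint-deduplicated collection of optimal solutions."""

    def __init__(
        self,
        z_star: int,
        reaction_ids: Sequence[str],
        method: str | None = None,
    ):
        self.z_star = int(z_star)
        self.reaction_ids = list(reaction_ids)
        self.method = method
        self.solutions: list[ImatSolution] = []
        self._fingerprints: set[bytes] = set()
        self.complete: bool = False  # True iff enumeration proved exhaustion
        self.stats: dict = {}
        self.config_echo: dict | None = None

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self):
        return iter(self.solutions)

    def add(self, solution: ImatSolution) -> bool:
        """Append unless an identical activity vector is already present."""
        fp = solution.fingerprint
        if fp is None or fp in self._fingerprints:
            return False
        self._fingerprints.add(fp)
        self.solutions.append(solution)
        return True

    def __contains__(self, activity) -> bool:
        return np.asarray(activity, dtype=np.uint8).tobytes() in self._fingerprints

    def activity_matrix(self) -> np.ndarray:
        if not self.solutions:
            return np.zeros((0, len(self.reaction_ids)), dtype=np.int8)
        return np.vstack([s.activity for s in self.solutions])


@dataclass(frozen=True)
class IntegerCut:
    """Linear constraint excluding one 0/1 vector: Σ_A x − Σ_B x ≤ Σx* − 1."""

    source: tuple[int, ...]  # the excluded activity vector x*
    ones: tuple[int, ...]  # A = {i | x*_i = 1}
    zeros: tuple[int, ...]  # B = {i | x*_i = 0}
    rhs: int  # (Σ_i x*_i) − 1

    def satisfied_by(self, y: Sequence[int]) -> bool:
        y = np.asarray(y)
        return int(y[list(self.ones)].sum() - y[list(self.zeros)].sum()) <= self.rhs


def make_integer_cut(x_star: Sequence[int]) -> IntegerCut:
    x = np.asarray(x_star, dtype=int)
    ones = tuple(int(i) for i in np.nonzero(x == 1)[0])
    zeros = tuple(int(i) for i in np.nonzero(x == 0)[0])
    return IntegerCut(tuple(int(b) for b in x), ones, zeros, int(x.sum()) - 1)


def pick_probability(d_s: float, i: int) -> float:
    """Diversity-enum sampling schedule: 1 − d_s^i.

    d_s = 0 is the degenerate maximum-dissimilarity regime (probability 1 at
    every step), so that the method reduces exactly to maxdist behaviour.
    """
    if d_s == 0:
        return 1.0
    return 1.0 - d_s**i


# -- internals --------------------------------------------------------------


def _prepare_problem(
    model: MetabolicModel, partition: ReactionPartition, config: EnumerationConfig
) -> tuple[ImatProblem, ImatSolution]:
    problem = build_imat(model, partition, config.epsilon)
    add_activity_indicators(problem)
    reference = solve_imat(problem, config.solver)
    if reference.status != "optimal":
        raise InfeasibleProblemError(
            f"reference iMAT solve ended with status {reference.status!r}"
        )
    return problem, reference


def _add_cut(problem: ImatProblem, activity: Sequence[int]) -> IntegerCut:
    cut = make_integer_cut(activity)
    act = problem.act_idx
    coefs = {act[i]: 1.0 for i in cut.ones}
    coefs.update({act[i]: -1.0 for i in cut.zeros})
    problem.lp.add_row(coefs, -np.inf, float(cut.rhs))
    return cut


def _set_overlap_objective(problem: ImatProblem, target: Sequence[int]) -> None:
    """Objective g(x, y) = Σ_{j : y_j = 1} a_j, minimized."""
    act = problem.act_idx
    target = np.asarray(target)
    coefs = {act[int(j)]: 1.0 for j in np.nonzero(target == 1)[0]}
    problem.lp.set_objective(coefs, maximize=False)


class _Deadline:
    def __init__(self, max_wall_time: float | None):
        self.t0 = time.monotonic()
        self.limit = max_wall_time

    def exceeded(self) -> bool:
        return self.limit is not None and time.monotonic() - self.t0 > self.limit

    def elapsed(self) -> float:
        return time.monotonic() - self.t0


def _reaction_scan(
    problem: ImatProblem,
    reference: ImatSolution,
    config: EnumerationConfig,
    sset: SolutionSet,
    deadline: _Deadline,
) -> dict:
    """Single-reaction perturbation scan in model file order.

    For each reaction the state is flipped relative to the reference solution:
    active reactions are blocked ([0, 0] bounds), inactive ones are forced
    forward (lower bound ε), with an extra backward trial (upper bound −ε) for
    reversible reactions.  A perturbed solution is retained iff it still
    scores z*.
    """
    model = problem.model
    eps = problem.epsilon
    trials = 0
    skipped = 0
    discarded = 0
    for i, rxn in enumerate(model.reactions):
        if len(sset) >= config.max_solutions or deadline.exceeded():
            break
        vi = int(problem.v_idx[i])
        lb0, ub0 = problem.lp.get_var_bounds(vi)
        if reference.activity[i]:
            attempts = [("block", 0, (0.0, 0.0))]
        else:
            attempts = [("forward", 1, (eps, ub0))]
            if lb0 < 0 and ub0 > 0:
                attempts.append(("backward", 1, (lb0, -eps)))
        for _label, target, (lo, hi) in attempts:
            if len(sset) >= config.max_solutions or deadline.exceeded():
                break
            if config.track_states and any(
                s.activity[i] == target for s in sset.solutions
            ):
                skipped += 1
                continue
            problem.lp.set_var_bounds(vi, lo, hi)
            try:
                trial = solve_imat(problem, config.solver)
            finally:
                problem.lp.set_var_bounds(vi, lb0, ub0)
            trials += 1
            if trial.status == "optimal" and trial.score == sset.z_star:
                if not sset.add(trial):
                    discarded += 1
            else:
                discarded += 1
    return {"trials": trials, "skipped": skipped, "discarded": discarded}


# -- strategies -------------------------------------------------------------


def reaction_enum(
    model: MetabolicModel,
    partition: ReactionPartition,
    config: EnumerationConfig | None = None,
) -> SolutionSet:
    """Single-reaction state-flip enumeration around a reference optimum."""
    config = config or EnumerationConfig(method="reaction")
    deadline = _Deadline(config.max_wall_time)
    problem, reference = _prepare_problem(model, partition, config)
    sset = SolutionSet(reference.score, model.reaction_ids, method="reaction")
    sset.add(reference)
    scan_stats = _reaction_scan(problem, reference, config, sset, deadline)
    sset.stats = {**scan_stats, "wall_time": deadline.elapsed()}
    sset.complete = True  # the scan itself finished; Ω* coverage is partial by design
    sset.config_echo = asdict(config)
    return sset


def icut_enum(
    model: MetabolicModel,
    partition: ReactionPartition,
    config: EnumerationConfig | None = None,
) -> SolutionSet:
    """Exhaustive enumeration by integer cuts, run until infeasibility."""
    config = config or EnumerationConfig(method="icut")
    deadline = _Deadline(config.max_wall_time)
    problem, reference = _prepare_problem(model, partition, config)
    sset = SolutionSet(reference.score, model.reaction_ids, method="icut")
    sset.add(reference)
    add_optimality_constraint(problem, sset.z_star)
    _add_cut(problem, reference.activity)
    solves = 1
    while len(sset) < config.max_solutions and not deadline.exceeded():
        sol = solve_imat(problem, config.solver)
        solves += 1
        if sol.status == "infeasible":
            sset.complete = True  # Ω* fully enumerated
            break
        if sol.status == "timeout":
            warnings.warn(
                "icut_enum stopped early on a solver timeout; the set is a "
                "partial sample, not a proved-complete enumeration"
            )
            break
        if not sset.add(sol):  # cut guarantees novelty; guard against stalls
            warnings.warn("icut_enum received an already-cut solution; stopping")
            break
        _add_cut(problem, sol.activity)
    sset.stats = {"solves": solves, "wall_time": deadline.elapsed()}
    sset.config_echo = asdict(config)
    return sset


def maxdist_enum(
    model: MetabolicModel,
    partition: ReactionPartition,
    config: EnumerationConfig | None = None,
    initial_cuts: Iterable[Sequence[int]] | None = None,
    reference_activity: Sequence[int] | None = None,
) -> SolutionSet:
    """Maximum-dissimilarity enumeration with integer cuts.

    ``initial_cuts`` installs cuts for externally known solutions without
    including them in the output; ``reference_activity`` overrides the starting
    solution (both default to a fresh reference optimum, which is included).
    """
    config = config or EnumerationConfig(method="maxdist")
    deadline = _Deadline(config.max_wall_time)
    problem, reference = _prepare_problem(model, partition, config)
    sset = SolutionSet(reference.score, model.reaction_ids, method="maxdist")
    add_optimality_constraint(problem, sset.z_star)
    if initial_cuts is not None:
        for vec in initial_cuts:
            _add_cut(problem, vec)
    if reference_activity is not None:
        current = np.asarray(reference_activity, dtype=np.int8)
    else:
        sset.add(reference)
        _add_cut(problem, reference.activity)
        current = reference.activity
    solves = 1
    while len(sset) < config.max_solutions and not deadline.exceeded():
        _set_overlap_objective(problem, current)
        sol = solve_imat(problem, config.solver)
        solves += 1
        if sol.status == "infeasible":
            sset.complete = True
            break
        if sol.status == "timeout":
            warnings.warn("maxdist_enum stopped early on a solver timeout")
            break
        if not sset.add(sol):
            warnings.warn("maxdist_enum received an already-cut solution; stopping")
            break
        _add_cut(problem, sol.activity)
        current = sol.activity
    sset.stats = {"solves": solves, "wall_time": deadline.elapsed()}
    sset.config_echo = asdict(config)
    return sset


def diversity_enum(
    model: MetabolicModel,
    partition: ReactionPartition,
    config: EnumerationConfig | None = None,
) -> SolutionSet:
    """Diversity-driven enumeration (reaction-enum seed + distance schedule).

    Phase 1 seeds the set with the reaction-enum scan and installs an integer
    cut per seed solution.  Phase 2 iterates: with i = 0, 1, 2, … each active
    reaction of the current solution enters the dissimilarity target y
    independently with probability 1 − d_s^i, and the MILP minimizes the
    overlap with y subject to the optimality equality and all cuts.  The
    schedule starts near the current solution (empty y: the cut alone drives
    novelty) and converges to full maxdist behaviour as i grows.
    """
    config = config or EnumerationConfig(method="diversity")
    deadline = _Deadline(config.max_wall_time)
    problem, reference = _prepare_problem(model, partition, config)
    sset = SolutionSet(reference.score, model.reaction_ids, method="diversity")
    sset.add(reference)
    scan_stats = _reaction_scan(problem, reference, config, sset, deadline)

    add_optimality_constraint(problem, sset.z_star)
    for sol in sset.solutions:
        _add_cut(problem, sol.activity)

    rng = np.random.default_rng(config.seed)
    current = sset.solutions[-1].activity  # last seed solution
    i = 0
    solves = 1 + scan_stats["trials"]
    while len(sset) < config.max_solutions and not deadline.exceeded():
        prob_pick = pick_probability(config.d_s, i)
        target = np.zeros_like(current)
        for j in np.nonzero(current == 1)[0]:  # reaction-index order
            if rng.random() <= prob_pick:
                target[j] = 1
        _set_overlap_objective(problem, target)
        sol = solve_imat(problem, config.solver)
        solves += 1
        if sol.status == "infeasible":
            sset.complete = True
            break
        if sol.status == "timeout":
            warnings.warn("diversity_enum stopped early on a solver timeout")
            break
        if not sset.add(sol):
            warnings.warn("diversity_enum received an already-cut solution; stopping")
            break
        _add_cut(problem, sol.activity)
        current = sol.activity
        i += 1
    sset.stats = {
        **scan_stats,
        "solves": solves,
        "phase2_iterations": i,
        "wall_time": deadline.elapsed(),
    }
    sset.config_echo = asdict(config)
    return sset


STRATEGIES = {
    "reaction": reaction_enum,
    "icut": icut_enum,
    "maxdist": maxdist_enum,
    "diversity": diversity_enum,
}


def enumerate_solutions(
    model: MetabolicModel,
    partition: ReactionPartition,
    config: EnumerationConfig,
) -> SolutionSet:
    """Dispatch to the strategy named in ``config.method``."""
    try:
        strategy = STRATEGIES[config.method]
    except KeyError:
        raise ValueError(
            f"unknown enumeration method {config.method!r}; "
            f"available: {sorted(STRATEGIES)}"
        ) from None
    return strategy(model, partition, config)


# -- persistence ------------------------------------------------------------


def _sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".yml")


def save_solution_set(
    sset: SolutionSet, path: str | Path, include_fluxes: bool = False
) -> None:
    """Write the activity matrix as CSV plus a YAML sidecar with metadata."""
    path = Path(path)
    frame = pd.DataFrame(
        sset.activity_matrix(),
        index=[f"solution_{k}" for k in range(len(sset))],
        columns=sset.reaction_ids,
        dtype=int,
    )
    frame.to_csv(path)
    meta = {
        "z_star": sset.z_star,
        "method": sset.method,
        "complete": sset.complete,
        "statuses": [s.status for s in sset.solutions],
        "stats": {k: float(v) if isinstance(v, float) else v
                  for k, v in sset.stats.items()},
        "config": sset.config_echo,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    if include_fluxes:
        fluxes = pd.DataFrame(
            np.vstack([s.flux for s in sset.solutions])
            if sset.solutions
            else np.zeros((0, len(sset.reaction_ids))),
            index=frame.index,
            columns=sset.reaction_ids,
        )
        fluxes.to_csv(path.with_name(path.stem + "_fluxes.csv"))


def load_solution_set(path: str | Path) -> SolutionSet:
    path = Path(path)
    try:
        frame = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - delegated parse failures
        raise FormatError(f"cannot parse solution file {path}: {exc}") from exc
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    sset = SolutionSet(meta["z_star"], list(frame.columns), method=meta.get("method"))
    sset.complete = bool(meta.get("complete", False))
    sset.stats = meta.get("stats") or {}
    sset.config_echo = meta.get("config")
    statuses = meta.get("statuses") or ["optimal"] * len(frame)
    for (_, row), status in zip(frame.iterrows(), statuses):
        activity = row.to_numpy(dtype=np.int8)
        sset.add(
            ImatSolution(
                flux=None, activity=activity, score=sset.z_star, status=status
            )
        )
    return sset
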