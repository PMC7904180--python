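"""Layered-DAG benchmark with an analytically known optimal-solution set.

The generator builds a feed-forward metabolic network: a source metabolite
m_s feeds N metabolites in layer 1, every metabolite in layer k feeds every
metabolite in layer k+1, and layer L drains into a sink metabolite m_t.  One
boundary exchange imports into m_s and one exports out of m_t.  All reactions
are irreversible with bounds [0, bound].

Under the benchmark scenario (R_H = ∅, R_L = R, export flux forced to at least
ε) every optimal network is a single source-to-sink path plus the two
exchanges, and there are exactly N^L of them — one per choice of one
metabolite per layer.  This makes the instance a ground-truth oracle for the
enumeration strategies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .model import (
    FluxForcing,
    Metabolite,
    MetabolicModel,
    Reaction,
    ReactionPartition,
)

__all__ = [
    "DagSpec",
    "build_dag_model",
    "dag_scenario",
    "ground_truth_count",
    "enumerate_ground_truth",
    "IMPORT_ID",
    "EXPORT_ID",
]

IMPORT_ID = "EX_in"
EXPORT_ID = "EX_out"

# Activation threshold for the benchmark scenario.  It must sit far above
# (flux bound) x (solver integrality tolerance): with bounds [0, 1000] and a
# MIP tolerance near 1e-6, binaries resting a hair off their bounds can leak
# fluxes of order 1e-3, so a threshold at that scale would admit phantom
# sub-threshold routes.  eps = 1 keeps three orders of magnitude of headroom.
DAG_EPSILON = 1.0


@dataclass(frozen=True)
class DagSpec:
    layers: int  # L
    width: int  # N metabolites per layer
    epsilon: float = DAG_EPSILON  # sink-flux forcing / activation level
    bound: float = 1000.0

    def __post_init__(self) -> None:
        if self.layers < 1 or self.width < 1:
            raise ValueError("DagSpec requires layers >= 1 and width >= 1")

    @property
    def n_metabolites(self) -> int:
        return 2 + self.width * self.layers

    @property
    def n_internal_reactions(self) -> int:
        return 2 * self.width + self.width**2 * (self.layers - 1)

    @property
    def n_reactions(self) -> int:
        return self.n_internal_reactions + 2  # plus the two boundary exchanges


def _met(i: int, k: int) -> str:
    return f"m_{i}_{k}"


def _src_rxn(i: int) -> str:
    return f"R_s_{i}"


def _link_rxn(i: int, j: int, k: int) -> str:
    return f"R_{k}_{i}_{j}"  # m_{i,k} -> m_{j,k+1}


def _sink_rxn(i: int) -> str:
    return f"R_t_{i}"


def build_dag_model(spec: DagSpec) -> MetabolicModel:
    """Materialize the layered DAG as a :class:`MetabolicModel`."""
    N, L, b = spec.width, spec.layers, spec.bound
    metabolites = [Metabolite("m_s")]
    metabolites += [Metabolite(_met(i, k)) for k in range(1, L + 1) for i in range(1, N + 1)]
    metabolites.append(Metabolite("m_t"))

    def rxn(rid: str, stoich: dict[str, float]) -> Reaction:
        return Reaction(rid, stoich, lower_bound=0.0, upper_bound=b)

    reactions = [rxn(IMPORT_ID, {"m_s": 1.0})]
    reactions += [rxn(_src_rxn(i), {"m_s": -1.0, _met(i, 1): 1.0}) for i in range(1, N + 1)]
    for k in range(1, L):
        for i in range(1, N + 1):
            for j in range(1, N + 1):
                reactions.append(
                    rxn(_link_rxn(i, j, k), {_met(i, k): -1.0, _met(j, k + 1): 1.0})
                )
    reactions += [rxn(_sink_rxn(i), {_met(i, L): -1.0, "m_t": 1.0}) for i in range(1, N + 1)]
    reactions.append(rxn(EXPORT_ID, {"m_t": -1.0}))

    return MetabolicModel(
        metabolites,
        reactions,
        objective_reaction_id=EXPORT_ID,
        model_id=f"dag_L{L}_N{N}",
    )


def dag_scenario(model: MetabolicModel,
                 epsilon: float | None = None) -> tuple[ReactionPartition, FluxForcing]:
    """The benchmark conditions: R_H = ∅, R_L = R, nonzero source-to-sink flux.

    The returned forcing directive raises the export exchange's lower bound to
    ε so every feasible flux routes m_s → m_t; apply it with
    :func:`dexom.model.apply_flux_forcing` before building the MILP.
    """
    if epsilon is None:
        epsilon = DAG_EPSILON
    partition = ReactionPartition(rh=set(), rl=set(model.reaction_ids))
    return partition, FluxForcing(EXPORT_ID, epsilon)


def ground_truth_count(spec: DagSpec) -> int:
    """Number of optimal networks: one per choice of a metabolite per layer."""
    return spec.width**spec.layers


def enumerate_ground_truth(
    spec: DagSpec, model: MetabolicModel, cap: int = 10**6
) -> np.ndarray:
    """All N^L optimal activity vectors, by direct path construction.

    Returns a matrix of shape (N^L, n_reactions); rows are 0/1 activity
    vectors over the model's reaction ordering (a path through one metabolite
    per layer, both exchange reactions always active).
    """
    total = ground_truth_count(spec)
    if total > cap:
        raise ValueError(
            f"ground truth has {total} solutions, above the cap of {cap}"
        )
    index = {rid: i for i, rid in enumerate(model.reaction_ids)}
    N, L = spec.width, spec.layers
    vectors = np.zeros((total, model.n_reactions), dtype=np.int8)
    for row, path in enumerate(product(range(1, N + 1), repeat=L)):
        vectors[row, index[IMPORT_ID]] = 1
        vectors[row, index[EXPORT_ID]] = 1
        vectors[row, index[_src_rxn(path[0])]] = 1
        for k in range(1, L):
            vectors[row, index[_link_rxn(path[k - 1], path[k], k)]] = 1
        vectors[row, index[_sink_rxn(path[-1])]] = 1
    return vectors
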