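"""FBA-based gene essentiality on enumerated networks and their ensemble.

For each context-specific network (an activity vector over the generic model)
every gene is knocked out in turn: the reactions whose GPR becomes false are
bound-silenced and the biomass optimum is recomputed by flux balance analysis.
A gene is essential for that network when the knockout optimum drops below a
fraction (default 1%) of the network's own wild-type optimum.  Per-network
predictions are OR-combined into an ensemble prediction: a gene is
ensemble-essential if any network predicts it essential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .exceptions import InfeasibleProblemError, UndefinedEssentialityError
from .model import MetabolicModel, submodel_by_activity

__all__ = [
    "EssentialityPrediction",
    "ConfusionSummary",
    "fba_max",
    "knockout_reactions",
    "single_gene_deletion",
    "ensemble_predict",
    "confusion",
    "load_essential_genes",
]

DEFAULT_KO_RATIO = 0.01


def fba_max(model: MetabolicModel, objective_reaction: str | None = None) -> float:
    """LP optimum of max v_obj subject to S·v = 0 and the flux bounds."""
    rid = objective_reaction or model.objective_reaction_id
    if rid is None:
        raise ValueError("no objective reaction specified and none set on the model")
    j = model.reaction_index(rid)
    c = np.zeros(model.n_reactions)
    c[j] = -1.0  # linprog minimizes
    S = model.stoichiometric_matrix
    bounds = list(zip(model.lower_bounds(), model.upper_bounds()))
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status == 2:
        raise InfeasibleProblemError(
            f"FBA LP infeasible for model {model.model_id!r} (this is distinct "
            "from a feasible model with zero objective flux)"
        )
    if not res.success:
        raise InfeasibleProblemError(f"FBA LP failed: {res.message}")
    return float(-res.fun)


def knockout_reactions(model: MetabolicModel, gene: str) -> set[str]:
    """Reactions disabled by deleting *gene* (GPR evaluates to false)."""
    if gene not in model.gene_ids:
        warnings.warn(f"gene {gene!r} is not in the model; knockout has no effect")
        return set()
    knocked = set()
    for rxn in model.reactions:
        if rxn.gpr is not None and gene in rxn.gpr.genes():
            if not rxn.gpr.evaluate_boolean(deleted={gene}):
                knocked.add(rxn.id)
    return knocked


def single_gene_deletion(
    model: MetabolicModel,
    gene: str,
    threshold_ratio: float = DEFAULT_KO_RATIO,
    wild_type: float | None = None,
    objective_reaction: str | None = None,
) -> bool:
    """True iff deleting *gene* drops the objective below threshold × wild type."""
    if wild_type is None:
        wild_type = fba_max(model, objective_reaction)
    if wild_type <= 0:
        raise UndefinedEssentialityError(
            "essentiality is undefined for a network with zero wild-type objective"
        )
    knocked = knockout_reactions(model, gene)
    if not knocked:
        return False
    ko_model = model.copy()
    for rid in knocked:
        rxn = ko_model.reaction(rid)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    ko_optimum = fba_max(ko_model, objective_reaction)
    return ko_optimum < threshold_ratio * wild_type


@dataclass
class EssentialityPrediction:
    per_network: pd.DataFrame  # networks × genes, boolean
    ensemble: dict[str, bool]  # OR over networks
    wild_type: list[float]  # wild-type objective per included network
    excluded: list[int] = field(default_factory=list)  # zero-WT network indices


def ensemble_predict(
    solution_set,
    model: MetabolicModel,
    genes: Iterable[str] | None = None,
    threshold_ratio: float = DEFAULT_KO_RATIO,
    objective_reaction: str | None = None,
) -> EssentialityPrediction:
    """Single-gene deletions on every network's submodel, OR-combined.

    Networks whose submodel has a zero (or infeasible) wild-type objective are
    excluded from the ensemble and recorded.
    """
    genes = sorted(genes) if genes is not None else sorted(model.gene_ids)
    rows, wts, kept, excluded = [], [], [], []
    for k, sol in enumerate(solution_set):
        submodel = submodel_by_activity(model, sol.activity)
        try:
            wt = fba_max(submodel, objective_reaction)
        except InfeasibleProblemError:
            wt = 0.0
        if wt <= 0:
            warnings.warn(f"network {k} has zero wild-type objective; excluded")
            excluded.append(k)
            continue
        rows.append(
            [
                single_gene_deletion(
                    submodel, g, threshold_ratio, wild_type=wt,
                    objective_reaction=objective_reaction,
                )
                for g in genes
            ]
        )
        wts.append(wt)
        kept.append(k)
    per_network = pd.DataFrame(
        rows, index=[f"network_{k}" for k in kept], columns=genes, dtype=bool
    )
    ensemble = {
        g: bool(per_network[g].any()) if len(per_network) else False for g in genes
    }
    return EssentialityPrediction(per_network, ensemble, wts, excluded)


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    n_skipped: int = 0  # predicted genes absent from the truth table

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) > 0 else float("nan")


def confusion(
    predictions: Mapping[str, bool], truth: Mapping[str, bool]
) -> ConfusionSummary:
    """TPR/FPR of boolean predictions against a curated truth table.

    Genes absent from the truth table are excluded from the counts and
    reported via ``n_skipped``.
    """
    common = [g for g in predictions if g in truth]
    if not common:
        raise ValueError("no overlap between predicted genes and the truth table")
    tp = fp = tn = fn = 0
    for g in common:
        if predictions[g] and truth[g]:
            tp += 1
        elif predictions[g] and not truth[g]:
            fp += 1
        elif not predictions[g] and truth[g]:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(tp, fp, tn, fn, n_skipped=len(predictions) - len(common))


def load_essential_genes(path: str | Path) -> dict[str, bool]:
    """Read a curated essential-gene TSV with columns gene_id, essential (0/1)."""
    frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame["gene_id"].astype(str), frame["essential"].astype(bool)))
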