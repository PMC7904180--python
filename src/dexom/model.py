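"""Data model and I/O for genome-scale metabolic networks.

A :class:`MetabolicModel` is the classic constraint-based triple (reactions,
metabolites, stoichiometric matrix S) with per-reaction flux bounds, optional
GPR rules and subsystem annotations.  Models are read from SBML Level 3 (FBC)
or from a flat cobra-style JSON dialect, and written back to the JSON dialect.

Reactions predicted inactive in a context are *bound-silenced* (both bounds set
to zero) rather than removed, so activity vectors stay index-aligned across all
solutions of an enumeration run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .exceptions import DimensionError, FormatError, ValidationError
from .gpr import GprNode, gpr_to_string, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ReactionPartition",
    "FluxForcing",
    "load_model",
    "save_model_json",
    "validate",
    "submodel_by_activity",
    "apply_flux_forcing",
]

DEFAULT_BOUND = 1000.0


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str | None = None


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GprNode | None = None
    subsystem: str | None = None
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 and self.upper_bound > 0

    @property
    def blocked(self) -> bool:
        return self.lower_bound == 0 and self.upper_bound == 0


class MetabolicModel:
    """Ordered collection of metabolites and reactions with stoichiometry S."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        objective_reaction_id: str | None = None,
        gene_ids: set[str] | None = None,
        model_id: str = "model",
        stoichiometric_matrix: np.ndarray | None = None,
    ):
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.objective_reaction_id = objective_reaction_id
        self.model_id = model_id
        if gene_ids is None:
            gene_ids = set()
            for rxn in self.reactions:
                if rxn.gpr is not None:
                    gene_ids |= rxn.gpr.genes()
        self.gene_ids = set(gene_ids)
        self._S = stoichiometric_matrix

    # -- indexing -----------------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    def reaction(self, reaction_id: str) -> Reaction:
        return self.reactions[self.reaction_index(reaction_id)]

    def computed_stoichiometric_matrix(self) -> np.ndarray:
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((self.n_metabolites, self.n_reactions))
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                if met_id not in met_index:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
                S[met_index[met_id], j] = coef
        return S

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        if self._S is not None:
            return self._S
        return self.computed_stoichiometric_matrix()

    def lower_bounds(self) -> np.ndarray:
        return np.array([r.lower_bound for r in self.reactions], dtype=float)

    def upper_bounds(self) -> np.ndarray:
        return np.array([r.upper_bound for r in self.reactions], dtype=float)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            [replace(m) for m in self.metabolites],
            [replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            objective_reaction_id=self.objective_reaction_id,
            gene_ids=set(self.gene_ids),
            model_id=self.model_id,
            stoichiometric_matrix=None if self._S is None else self._S.copy(),
        )


@dataclass
class ReactionPartition:
    """Disjoint R_H (highly-expressed) / R_L (lowly-expressed) reaction sets."""

    rh: set[str] = field(default_factory=set)
    rl: set[str] = field(default_factory=set)

    def validate_for(self, model: MetabolicModel) -> None:
        if self.rh & self.rl:
            raise ValidationError(
                f"R_H and R_L overlap: {sorted(self.rh & self.rl)[:5]}"
            )
        unknown = (self.rh | self.rl) - set(model.reaction_ids)
        if unknown:
            raise ValidationError(
                f"partition references unknown reactions: {sorted(unknown)[:5]}"
            )


class FluxForcing(NamedTuple):
    """Directive to raise one reaction's lower bound (e.g. force sink flux)."""

    reaction_id: str
    lower_bound: float


def apply_flux_forcing(model: MetabolicModel, forcing: FluxForcing) -> MetabolicModel:
    """Return a copy of *model* with the forcing reaction's lower bound raised."""
    out = model.copy()
    rxn = out.reaction(forcing.reaction_id)
    rxn.lower_bound = max(rxn.lower_bound, forcing.lower_bound)
    return out


# -- validation -------------------------------------------------------------


def validate(model: MetabolicModel) -> list[str]:
    """Check the model invariants; returns one finding string per violation."""
    findings: list[str] = []
    seen_m: set[str] = set()
    for met in model.metabolites:
        if met.id in seen_m:
            findings.append(f"duplicate metabolite id {met.id!r}")
        seen_m.add(met.id)
    seen_r: set[str] = set()
    for rxn in model.reactions:
        if rxn.id in seen_r:
            findings.append(f"duplicate reaction id {rxn.id!r}")
        seen_r.add(rxn.id)
        if rxn.lower_bound > rxn.upper_bound:
            findings.append(
                f"reaction {rxn.id!r} has lower_bound {rxn.lower_bound} > "
                f"upper_bound {rxn.upper_bound}"
            )
        for met_id in rxn.stoichiometry:
            if met_id not in seen_m and met_id not in model.metabolite_ids:
                findings.append(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        if rxn.gpr is not None:
            missing = rxn.gpr.genes() - model.gene_ids
            if missing:
                findings.append(
                    f"reaction {rxn.id!r} GPR uses genes not in gene_ids: "
                    f"{sorted(missing)}"
                )
    if model._S is not None:
        try:
            computed = model.computed_stoichiometric_matrix()
        except ValidationError:
            computed = None
        if computed is not None:
            if model._S.shape != computed.shape:
                findings.append(
                    f"stored S has shape {model._S.shape}, expected {computed.shape}"
                )
            else:
                bad = np.where(np.any(model._S != computed, axis=0))[0]
                for j in bad:
                    findings.append(
                        f"S column for reaction {model.reactions[j].id!r} is "
                        "inconsistent with its stoichiometry"
                    )
    return findings


# -- context sub-models -----------------------------------------------------


def submodel_by_activity(model: MetabolicModel, activity: Sequence[int]) -> MetabolicModel:
    """Bound-silence every reaction whose activity bit is 0.

    The returned copy shares the reaction ordering and stoichiometry of the
    input, so activity vectors remain index-aligned.
    """
    activity = np.asarray(activity)
    if activity.shape != (model.n_reactions,):
        raise DimensionError(
            f"activity vector has length {activity.shape}, model has "
            f"{model.n_reactions} reactions"
        )
    out = model.copy()
    for bit, rxn in zip(activity, out.reactions):
        if not bit:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


# -- JSON dialect -----------------------------------------------------------


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.model_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": gpr_to_string(r.gpr),
                "subsystem": r.subsystem or "",
                "objective_coefficient": (
                    1.0 if r.id == model.objective_reaction_id else 0.0
                ),
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in sorted(model.gene_ids)],
    }


def save_model_json(model: MetabolicModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=1, sort_keys=True))


def _model_from_dict(data: dict) -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(m["id"], m.get("name", "") or "", m.get("compartment"))
            for m in data["metabolites"]
        ]
        objective = None
        reactions = []
        for r in data["reactions"]:
            reactions.append(
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r.get("metabolites", {}).items()},
                    lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                    upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                    gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                    subsystem=r.get("subsystem") or None,
                    name=r.get("name", "") or "",
                )
            )
            if r.get("objective_coefficient"):
                objective = r["id"]
        genes = {g["id"] for g in data.get("genes", [])}
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed JSON model: missing element {exc}") from exc
    model = MetabolicModel(
        metabolites,
        reactions,
        objective_reaction_id=objective,
        gene_ids=genes or None,
        model_id=data.get("id", "model"),
    )
    _raise_on_duplicates(model)
    return model


def _raise_on_duplicates(model: MetabolicModel) -> None:
    findings = [f for f in validate(model) if f.startswith("duplicate")]
    if findings:
        raise ValidationError("; ".join(findings))


# -- SBML -------------------------------------------------------------------


def _load_sbml(path: str | Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"SBML parse failure: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"no <model> element in SBML file {path}")

    metabolites = [
        Metabolite(sp.getId(), sp.getName() or "", sp.getCompartment() or None)
        for sp in sbml_model.getListOfSpecies()
    ]

    params = {
        p.getId(): p.getValue() for p in sbml_model.getListOfParameters()
    }

    def bound_value(param_id: str | None, default: float) -> float:
        if param_id and param_id in params:
            return params[param_id]
        return default

    reactions: list[Reaction] = []
    objective = None
    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None:
        active = mplug.getActiveObjective()
        if active is not None and active.getNumFluxObjectives() > 0:
            objective = active.getFluxObjective(0).getReaction()

    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = rxn.getPlugin("fbc")
        default_lb = -DEFAULT_BOUND if rxn.getReversible() else 0.0
        lb, ub = default_lb, DEFAULT_BOUND
        gpr = None
        if rplug is not None:
            lb = bound_value(rplug.getLowerFluxBound() or None, default_lb)
            ub = bound_value(rplug.getUpperFluxBound() or None, DEFAULT_BOUND)
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gpr = _convert_association(gpa.getAssociation())
        reactions.append(
            Reaction(
                id=rxn.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                subsystem=None,
                name=rxn.getName() or "",
            )
        )

    model = MetabolicModel(
        metabolites,
        reactions,
        objective_reaction_id=objective,
        model_id=sbml_model.getId() or "model",
    )
    _raise_on_duplicates(model)
    return model


def _convert_association(assoc) -> GprNode | None:
    import libsbml

    from .gpr import GprAnd, GprGene, GprOr

    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        return GprGene(assoc.getGeneProduct())
    children = tuple(
        c
        for c in (
            _convert_association(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        )
        if c is not None
    )
    if isinstance(assoc, libsbml.FbcAnd):
        return GprAnd(children)
    if isinstance(assoc, libsbml.FbcOr):
        return GprOr(children)
    raise FormatError(f"unsupported GPR association element {type(assoc).__name__}")


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from SBML (L3+FBC) or the JSON dialect.

    *format* is ``"sbml"`` or ``"json"``; when omitted it is inferred from the
    file extension.
    """
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid JSON in {path}: {exc}") from exc
        return _model_from_dict(data)
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown model format {format!r}")
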