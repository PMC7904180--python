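import numpy as np
import pytest

from dexom import (
    DagSpec,
    EnumerationConfig,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionPartition,
    apply_flux_forcing,
    build_dag_model,
    dag_scenario,
    parse_gpr,
)


def make_reaction(rid, stoich, lb=0.0, ub=1000.0, gpr=None, subsystem=None):
    return Reaction(rid, stoich, lower_bound=lb, upper_bound=ub,
                    gpr=parse_gpr(gpr), subsystem=subsystem)


@pytest.fixture
def dag22():
    """DAG with 2 layers x 2 metabolites: 4 optimal path networks."""
    spec = DagSpec(layers=2, width=2)
    model = build_dag_model(spec)
    partition, forcing = dag_scenario(model, spec.epsilon)
    forced = apply_flux_forcing(model, forcing)
    return spec, model, forced, partition


def dag_instance(layers, width):
    spec = DagSpec(layers=layers, width=width)
    model = build_dag_model(spec)
    partition, forcing = dag_scenario(model, spec.epsilon)
    forced = apply_flux_forcing(model, forcing)
    return spec, model, forced, partition


def enum_config(spec, **kwargs):
    kwargs.setdefault("epsilon", spec.epsilon)
    kwargs.setdefault("max_solutions", 100000)
    return EnumerationConfig(**kwargs)


@pytest.fixture
def parallel_paths_model():
    """Two parallel A->B routes with distinct genes, then a shared step.

    EX_A -> A; R1/R2: A -> B (isoenzyme-like parallel reactions, genes g1/g2);
    R3: B -> C (complex g3 and g4); BIOMASS: C ->.  Deleting g1 leaves R2 as a
    backup; deleting g3 (or g4) blocks the only route to biomass.
    """
    mets = [Metabolite(m) for m in ("A", "B", "C")]
    rxns = [
        make_reaction("EX_A", {"A": 1.0}, ub=10.0),
        make_reaction("R1", {"A": -1.0, "B": 1.0}, gpr="g1"),
        make_reaction("R2", {"A": -1.0, "B": 1.0}, gpr="g2"),
        make_reaction("R3", {"B": -1.0, "C": 1.0}, gpr="g3 and g4"),
        make_reaction("BIOMASS", {"C": -1.0}),
    ]
    return MetabolicModel(mets, rxns, objective_reaction_id="BIOMASS")


def oracle_fingerprints(spec, model):
    from dexom import enumerate_ground_truth

    return {v.tobytes() for v in enumerate_ground_truth(spec, model).astype(np.uint8)}
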