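"""Model container, GPR parsing, I/O round trips, and validation."""

import numpy as np
import pytest

from dexom import (
    DagSpec,
    GprAnd,
    GprGene,
    GprOr,
    MetabolicModel,
    Metabolite,
    Reaction,
    build_dag_model,
    fba_max,
    load_model,
    parse_gpr,
    save_model_json,
    submodel_by_activity,
    validate,
)
from dexom.exceptions import DimensionError, FormatError, ValidationError
from conftest import make_reaction


class TestGprParsing:
    def test_nested_and_or_tree(self):
        tree = parse_gpr("(g1 and g2) or g3")
        assert tree == GprOr((GprAnd((GprGene("g1"), GprGene("g2"))), GprGene("g3")))

    def test_keywords_case_insensitive(self):
        assert parse_gpr("g1 AND g2") == parse_gpr("g1 and g2")

    def test_empty_rule_is_none(self):
        assert parse_gpr("") is None
        assert parse_gpr(None) is None

    @pytest.mark.parametrize("bad", ["(g1 and", "g1 or or g2", "and g1", "g1 g2"])
    def test_malformed_rules_raise(self, bad):
        with pytest.raises(FormatError):
            parse_gpr(bad)

    def test_boolean_eval_matches_cobra(self):
        from cobra.core.gene import GPR

        rules = ["(g1 and g2) or g3", "g1 or (g2 and (g3 or g4))", "g1 and g2 and g3"]
        deletions = [set(), {"g1"}, {"g1", "g3"}, {"g2", "g4"}, {"g1", "g2", "g3", "g4"}]
        for rule in rules:
            ours = parse_gpr(rule)
            theirs = GPR.from_string(rule)
            for deleted in deletions:
                assert ours.evaluate_boolean(deleted) == theirs.eval(knockouts=deleted)


class TestJsonRoundTrip:
    def test_dag_model_round_trip_identity(self, tmp_path):
        model = build_dag_model(DagSpec(layers=3, width=2))
        path = tmp_path / "dag.json"
        save_model_json(model, path)
        back = load_model(path, format="json")
        assert back.reaction_ids == model.reaction_ids
        assert back.metabolite_ids == model.metabolite_ids
        assert np.array_equal(back.lower_bounds(), model.lower_bounds())
        assert np.array_equal(back.upper_bounds(), model.upper_bounds())
        assert np.array_equal(
            back.stoichiometric_matrix, model.stoichiometric_matrix
        )

    def test_save_load_save_is_idempotent(self, tmp_path):
        model = build_dag_model(DagSpec(layers=2, width=2))
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_model_json(model, p1)
        save_model_json(load_model(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_gpr_and_objective_survive(self, tmp_path):
        model = MetabolicModel(
            [Metabolite("A"), Metabolite("B")],
            [
                make_reaction("R1", {"A": -1.0, "B": 1.0}, gpr="(g1 and g2) or g3"),
                make_reaction("EX_A", {"A": 1.0}),
                make_reaction("EX_B", {"B": -1.0}),
            ],
            objective_reaction_id="EX_B",
        )
        path = tmp_path / "m.json"
        save_model_json(model, path)
        back = load_model(path)
        assert back.reaction("R1").gpr == model.reaction("R1").gpr
        assert back.objective_reaction_id == "EX_B"
        assert back.gene_ids == {"g1", "g2", "g3"}

    def test_missing_bounds_default(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(
            '{"metabolites": [{"id": "A"}], '
            '"reactions": [{"id": "R", "metabolites": {"A": 1}}]}'
        )
        model = load_model(path)
        assert model.reaction("R").lower_bound == -1000
        assert model.reaction("R").upper_bound == 1000

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.json"
        path.write_text(
            '{"metabolites": [{"id": "A"}], "reactions": '
            '[{"id": "R", "metabolites": {}}, {"id": "R", "metabolites": {}}]}'
        )
        with pytest.raises(ValidationError):
            load_model(path)

    def test_garbage_json_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(FormatError):
            load_model(path)


class TestSbml:
    def _write_reference_sbml(self, path):
        import cobra

        m = cobra.Model("tiny")
        A = cobra.Metabolite("A", compartment="c")
        B = cobra.Metabolite("B", compartment="c")
        r = cobra.Reaction("R1")
        r.add_metabolites({A: -1, B: 1})
        r.bounds = (0, 1000)
        r.gene_reaction_rule = "(g1 and g2) or g3"
        ex_a = cobra.Reaction("EX_A")
        ex_a.add_metabolites({A: 1})
        ex_a.bounds = (0, 1000)
        ex_b = cobra.Reaction("EX_B")
        ex_b.add_metabolites({B: -1})
        ex_b.bounds = (-5, 1000)
        m.add_reactions([r, ex_a, ex_b])
        cobra.io.write_sbml_model(m, str(path))

    def test_single_conversion_reaction(self, tmp_path):
        path = tmp_path / "tiny.xml"
        self._write_reference_sbml(path)
        model = load_model(path, format="sbml")
        assert model.n_reactions == 3 and model.n_metabolites == 2
        j = model.reaction_index("R_R1")
        col = model.stoichiometric_matrix[:, j]
        assert sorted(col) == [-1.0, 1.0]
        assert model.reaction("R_R1").lower_bound == 0
        assert model.reaction("R_R1").upper_bound == 1000
        assert model.reaction("R_EX_B").lower_bound == -5

    def test_gpr_tree_from_fbc(self, tmp_path):
        path = tmp_path / "tiny.xml"
        self._write_reference_sbml(path)
        model = load_model(path)
        assert model.reaction("R_R1").gpr == GprOr(
            (GprAnd((GprGene("G_g1"), GprGene("G_g2"))), GprGene("G_g3"))
        )

    def test_unparseable_file_raises(self, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<sbml><model></sbml>")
        with pytest.raises(FormatError):
            load_model(path, format="sbml")


class TestValidate:
    def test_valid_dag_model_has_no_findings(self):
        assert validate(build_dag_model(DagSpec(layers=2, width=2))) == []

    def test_inverted_bounds_reported(self):
        model = MetabolicModel(
            [Metabolite("A")],
            [Reaction("R", {"A": 1.0}, lower_bound=5, upper_bound=1)],
        )
        findings = validate(model)
        assert len(findings) == 1 and "R" in findings[0]

    def test_inconsistent_stored_matrix_detected(self):
        model = build_dag_model(DagSpec(layers=2, width=2))
        S = model.computed_stoichiometric_matrix()
        S[0, 0] += 1.0  # corrupt one column
        tampered = MetabolicModel(
            model.metabolites, model.reactions, stoichiometric_matrix=S
        )
        findings = validate(tampered)
        assert len(findings) == 1
        assert model.reactions[0].id in findings[0]


class TestSubmodel:
    def test_all_ones_keeps_bounds(self, dag22):
        _, _, forced, _ = dag22
        sub = submodel_by_activity(forced, np.ones(forced.n_reactions, dtype=int))
        assert np.array_equal(sub.lower_bounds(), forced.lower_bounds())
        assert np.array_equal(sub.upper_bounds(), forced.upper_bounds())

    def test_all_zeros_silences_everything(self, dag22):
        _, _, forced, _ = dag22
        sub = submodel_by_activity(forced, np.zeros(forced.n_reactions, dtype=int))
        assert np.all(sub.lower_bounds() == 0) and np.all(sub.upper_bounds() == 0)

    def test_stoichiometry_unchanged(self, dag22):
        _, _, forced, _ = dag22
        sub = submodel_by_activity(forced, np.zeros(forced.n_reactions, dtype=int))
        assert np.array_equal(
            sub.stoichiometric_matrix, forced.stoichiometric_matrix
        )

    def test_oracle_path_submodel_carries_flux(self, dag22):
        from dexom import enumerate_ground_truth

        spec, model, forced, _ = dag22
        vec = enumerate_ground_truth(spec, model)[0]
        sub = submodel_by_activity(forced, vec)
        assert fba_max(sub, "EX_out") >= spec.epsilon

    def test_length_mismatch_raises(self, dag22):
        _, _, forced, _ = dag22
        with pytest.raises(DimensionError):
            submodel_by_activity(forced, [1, 0])
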