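"""The four enumeration strategies, integer cuts, and persistence."""

import numpy as np
import pytest

from dexom import (
    EnumerationConfig,
    diversity_enum,
    icut_enum,
    load_solution_set,
    make_integer_cut,
    maxdist_enum,
    pick_probability,
    reaction_enum,
    save_solution_set,
)
from dexom.enumeration import _add_cut, _prepare_problem
from dexom.imat import add_optimality_constraint, solve_imat
from dexom.metrics import hamming
from conftest import dag_instance, enum_config, oracle_fingerprints


class TestIntegerCut:
    def test_cut_excludes_its_source(self):
        cut = make_integer_cut([1, 0, 1])
        assert cut.ones == (0, 2) and cut.zeros == (1,) and cut.rhs == 1
        assert not cut.satisfied_by([1, 0, 1])

    @pytest.mark.parametrize("other", [[1, 0, 0], [1, 1, 1], [0, 0, 0], [0, 1, 1]])
    def test_cut_admits_any_differing_vector(self, other):
        cut = make_integer_cut([1, 0, 1])
        assert cut.satisfied_by(other)

    @pytest.mark.parametrize("seed", range(20))
    def test_cut_property_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, size=30)
        cut = make_integer_cut(x)
        assert not cut.satisfied_by(x)
        for _ in range(10):
            y = x.copy()
            flips = rng.choice(30, size=rng.integers(1, 30), replace=False)
            y[flips] = 1 - y[flips]
            assert cut.satisfied_by(y)

    def test_resolve_never_returns_cut_solution(self, dag22):
        spec, _, forced, partition = dag22
        config = enum_config(spec)
        problem, reference = _prepare_problem(forced, partition, config)
        add_optimality_constraint(problem, reference.score)
        seen = {reference.fingerprint}
        _add_cut(problem, reference.activity)
        for _ in range(3):
            sol = solve_imat(problem, config.solver)
            assert sol.status == "optimal"
            assert sol.fingerprint not in seen
            seen.add(sol.fingerprint)
            _add_cut(problem, sol.activity)


class TestReactionEnum:
    def test_retained_subset_of_oracle(self, dag22):
        spec, model, forced, partition = dag22
        sset = reaction_enum(forced, partition, enum_config(spec, track_states=False))
        oracle = oracle_fingerprints(spec, model)
        assert {s.fingerprint for s in sset} <= oracle
        assert all(s.score == sset.z_star for s in sset)

    def test_trial_count_equals_reactions_when_untracked(self, dag22):
        spec, model, forced, partition = dag22
        sset = reaction_enum(forced, partition, enum_config(spec, track_states=False))
        assert sset.stats["trials"] == model.n_reactions  # all irreversible

    def test_state_tracking_skips_trials(self, dag22):
        spec, _, forced, partition = dag22
        tracked = reaction_enum(forced, partition, enum_config(spec, track_states=True))
        assert tracked.stats["skipped"] > 0
        assert tracked.stats["trials"] + tracked.stats["skipped"] >= 1

    def test_unique_optimum_yields_single_solution(self):
        spec, _, forced, partition = dag_instance(3, 1)  # width 1: unique path
        sset = reaction_enum(forced, partition, enum_config(spec, track_states=False))
        assert len(sset) == 1


class TestIcutEnum:
    def test_complete_enumeration_matches_oracle(self, dag22):
        spec, model, forced, partition = dag22
        sset = icut_enum(forced, partition, enum_config(spec))
        assert len(sset) == 4 and sset.complete
        assert {s.fingerprint for s in sset} == oracle_fingerprints(spec, model)

    def test_max_solutions_one_returns_default_optimum(self, dag22):
        spec, _, forced, partition = dag22
        sset = icut_enum(forced, partition, enum_config(spec, max_solutions=1))
        assert len(sset) == 1 and not sset.complete

    def test_all_scores_equal_z_star(self, dag22):
        spec, _, forced, partition = dag22
        sset = icut_enum(forced, partition, enum_config(spec))
        assert all(s.score == sset.z_star for s in sset)


class TestMaxdistEnum:
    def test_first_step_attains_max_hamming(self, dag22):
        spec, model, forced, partition = dag22
        sset = maxdist_enum(forced, partition, enum_config(spec, max_solutions=2))
        ref, far = sset.solutions
        oracle = np.asarray(
            [np.frombuffer(fp, dtype=np.uint8) for fp in oracle_fingerprints(spec, model)]
        )
        best = max(hamming(ref.activity, v) for v in oracle)
        assert hamming(ref.activity, far.activity) == pytest.approx(best)

    def test_complete_run_recovers_oracle(self, dag22):
        spec, model, forced, partition = dag22
        sset = maxdist_enum(forced, partition, enum_config(spec))
        assert sset.complete
        assert {s.fingerprint for s in sset} == oracle_fingerprints(spec, model)

    def test_no_duplicates_across_iterations(self, dag22):
        spec, _, forced, partition = dag22
        sset = maxdist_enum(forced, partition, enum_config(spec))
        fps = [s.fingerprint for s in sset]
        assert len(fps) == len(set(fps))


class TestDiversityEnum:
    def test_pick_prob_schedule_values(self):
        assert pick_probability(0.5, 0) == 0.0
        assert pick_probability(0.995, 0) == 0.0
        assert pick_probability(0.99, 70) == pytest.approx(0.5052, abs=1e-4)
        assert pick_probability(0, 0) == 1.0  # degenerate maxdist regime
        assert pick_probability(0, 5) == 1.0

    def test_fixed_seed_reproduces_sequence(self, dag22):
        spec, _, forced, partition = dag22
        a = diversity_enum(forced, partition, enum_config(spec, seed=11))
        b = diversity_enum(forced, partition, enum_config(spec, seed=11))
        assert [s.fingerprint for s in a] == [s.fingerprint for s in b]

    def test_complete_enumeration_on_small_instance(self, dag22):
        spec, model, forced, partition = dag22
        sset = diversity_enum(forced, partition, enum_config(spec, seed=3))
        assert {s.fingerprint for s in sset} == oracle_fingerprints(spec, model)

    def test_ds_zero_equals_maxdist_continuation(self):
        spec, model, forced, partition = dag_instance(3, 2)  # 8 solutions
        config = enum_config(spec, d_s=0.0, seed=5)
        dset = diversity_enum(forced, partition, config)
        # reproduce: same seed phase, then a maxdist continuation from the
        # last seed with the seed cuts installed
        seeds = reaction_enum(forced, partition, enum_config(spec, seed=5))
        k = len(seeds)
        mset = maxdist_enum(
            forced,
            partition,
            enum_config(spec, seed=5),
            initial_cuts=[s.activity for s in seeds],
            reference_activity=seeds.solutions[-1].activity,
        )
        assert [s.fingerprint for s in seeds] == [s.fingerprint for s in dset][:k]
        assert [s.fingerprint for s in mset] == [s.fingerprint for s in dset][k:]


class TestPersistence:
    def test_round_trip_preserves_fingerprints(self, dag22, tmp_path):
        spec, _, forced, partition = dag22
        sset = icut_enum(forced, partition, enum_config(spec))
        path = tmp_path / "solutions.csv"
        save_solution_set(sset, path)
        back = load_solution_set(path)
        assert [s.fingerprint for s in back] == [s.fingerprint for s in sset]
        assert back.z_star == sset.z_star
        assert [s.status for s in back] == [s.status for s in sset]
        assert back.complete == sset.complete

    def test_empty_set_round_trips(self, tmp_path):
        from dexom.enumeration import SolutionSet

        empty = SolutionSet(z_star=0, reaction_ids=["r1", "r2"], method="icut")
        path = tmp_path / "empty.csv"
        save_solution_set(empty, path)
        back = load_solution_set(path)
        assert len(back) == 0 and back.reaction_ids == ["r1", "r2"]

    def test_save_load_save_byte_identical(self, dag22, tmp_path):
        spec, _, forced, partition = dag22
        sset = icut_enum(forced, partition, enum_config(spec))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        save_solution_set(sset, p1)
        save_solution_set(load_solution_set(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()
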