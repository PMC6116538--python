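import numpy as np
import pytest

from mapclust import (
    DistanceMatrix,
    EAConfig,
    ParetoFront,
    ReferenceClasses,
    assign_followers,
    evaluate,
    merge_fronts,
    nsga2_run,
    repair,
    run_bilevel,
    select_per_k,
)
from mapclust.bilevel import MedoidSolution, nondominated_ranks
from _oracles import (
    exhaustive_follower,
    exhaustive_kmedoid_front,
    lp_follower,
    pareto_staircase,
)
from conftest import random_distance_matrix


def dm(values):
    values = np.array(values, float)
    return DistanceMatrix(labels=[f"n{i}" for i in range(len(values))],
                          values=values, metric="combined")


# Crafted asymmetric pair: element 2's d2-nearest medoid (0) is not its
# d1-nearest (1), so the exact follower hurts the leader.
D1 = dm([[0, 3, 5, 2], [3, 0, 1, 2], [5, 1, 0, 4], [2, 2, 4, 0]])
D2 = dm([[0, 3, 1, 2], [3, 0, 2, 9], [1, 2, 0, 4], [2, 9, 4, 0]])


class TestFollower:
    def test_single_medoid_owns_everything(self):
        bits = np.zeros(4, bool)
        bits[1] = True
        assignment = assign_followers(bits, D2)
        assert np.all(assignment == 1)

    def test_all_ones_self_assigns_with_zero_objective(self):
        bits = np.ones(4, bool)
        assignment, (inertia, k) = evaluate(bits, D2, D2)
        assert np.array_equal(assignment, np.arange(4))
        assert inertia == 0.0 and k == 4

    def test_matches_exhaustive_and_lp_oracles(self):
        rng = np.random.default_rng(12)
        m = random_distance_matrix(8, rng)
        bits = np.zeros(8, bool)
        bits[[2, 5]] = True
        assignment = assign_followers(bits, m)
        obj = m.values[np.arange(8), assignment].sum()
        oracle_assignment, oracle_obj = exhaustive_follower(bits, m.values)
        assert obj == pytest.approx(oracle_obj)
        assert np.array_equal(assignment, oracle_assignment)
        assert lp_follower(bits, m.values) == pytest.approx(obj)

    def test_all_zero_genome_is_error(self):
        with pytest.raises(ValueError, match="repair"):
            assign_followers(np.zeros(4, bool), D2)

    def test_ties_break_to_lowest_medoid_index(self):
        tie = dm([[0, 1, 1], [1, 0, 2], [1, 2, 0]])
        bits = np.array([False, True, True])
        assignment = assign_followers(bits, tie)
        assert assignment[0] == 1  # equidistant from medoids 1 and 2


class TestEvaluate:
    def test_exact_follower_can_hurt_the_leader(self):
        bits = np.zeros(4, bool)
        bits[[0, 1]] = True
        assignment, (inertia, k) = evaluate(bits, D1, D2)
        assert np.array_equal(assignment, [0, 1, 0, 0])
        assert inertia == 7.0  # element 2 pays d1(2,0)=5 although d1(2,1)=1
        single_level = sum(min(D1.values[i, 0], D1.values[i, 1]) for i in range(4))
        assert inertia > single_level == 3.0

    def test_adding_medoids_never_hurts_when_metrics_agree(self):
        rng = np.random.default_rng(3)
        m = random_distance_matrix(9, rng)
        bits = np.zeros(9, bool)
        bits[[1, 4]] = True
        _, (base, _) = evaluate(bits, m, m)
        for extra in (0, 6, 8):
            grown = bits.copy()
            grown[extra] = True
            _, (inertia, _) = evaluate(grown, m, m)
            assert inertia <= base + 1e-12

    def test_label_mismatch_is_error(self):
        other = DistanceMatrix(labels=["a", "b", "c", "d"],
                               values=D2.values.copy(), metric="combined")
        with pytest.raises(ValueError, match="labels"):
            evaluate(np.ones(4, bool), D1, other)


class TestRepair:
    def test_all_zero_gets_exactly_one_bit(self):
        rng = np.random.default_rng(0)
        out = repair(np.zeros(10, bool), rng)
        assert out.sum() == 1

    def test_nonzero_unchanged_and_idempotent(self):
        rng = np.random.default_rng(0)
        bits = np.zeros(10, bool)
        bits[3] = True
        assert repair(bits, rng) is bits
        fixed = repair(np.zeros(10, bool), rng)
        assert repair(fixed, rng) is fixed


class TestNSGA2:
    def test_front_is_mutually_nondominated(self):
        rng = np.random.default_rng(21)
        m1, m2 = random_distance_matrix(12, rng), random_distance_matrix(12, rng)
        front = nsga2_run(m1, m2, EAConfig.desk(rng_seed=1, generations=100,
                                                independent_runs=1))
        objs = np.array([[s.leader_inertia, s.n_clusters] for s in front.solutions])
        assert np.all(nondominated_ranks(objs) == 0)

    def test_matches_exhaustive_kmedoid_optima_single_metric(self):
        rng = np.random.default_rng(8)
        m = random_distance_matrix(10, rng)
        front = merge_fronts([
            nsga2_run(m, m, EAConfig(population_size=40, generations=500,
                                     independent_runs=1, rng_seed=seed))
            for seed in (101, 102, 103)
        ])
        oracle = exhaustive_kmedoid_front(m.values, m.values, k_max=3)
        staircase = dict(pareto_staircase(oracle))
        for k, opt in staircase.items():
            sol = front.solution_at_k(k)
            assert sol is not None
            assert sol.leader_inertia == pytest.approx(opt, abs=1e-9)

    def test_seeded_runs_are_bit_identical(self):
        rng = np.random.default_rng(30)
        m1, m2 = random_distance_matrix(10, rng), random_distance_matrix(10, rng)
        cfg = EAConfig.desk(rng_seed=77, generations=120, independent_runs=1)
        f1, f2 = nsga2_run(m1, m2, cfg), nsga2_run(m1, m2, cfg)
        assert len(f1.solutions) == len(f2.solutions)
        for a, b in zip(f1.sorted_by_k(), f2.sorted_by_k()):
            assert np.array_equal(a.bits, b.bits)
            assert a.leader_inertia == b.leader_inertia

    def test_degenerate_anchor_points(self):
        rng = np.random.default_rng(14)
        m = random_distance_matrix(8, rng)
        front = run_bilevel(m, m, EAConfig.desk(rng_seed=5, generations=300,
                                                independent_runs=2))
        full = front.solution_at_k(8)
        assert full is not None and full.leader_inertia == 0.0
        k1 = front.solution_at_k(1)
        assert k1 is not None
        best_single = min(m.values[:, j].sum() for j in range(8))
        assert k1.leader_inertia == pytest.approx(best_single)

    def test_swapping_leader_and_follower_changes_the_front(self):
        cfg = EAConfig.desk(rng_seed=9, generations=200, independent_runs=2,
                            population_size=20)
        f12 = run_bilevel(D1, D2, cfg)
        f21 = run_bilevel(D2, D1, cfg)
        assert f12.objective_set() != f21.objective_set()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EAConfig(population_size=7)
        with pytest.raises(ValueError):
            EAConfig(crossover_prob=1.5)


class TestFrontOperations:
    def make_solution(self, n, medoids, inertia):
        bits = np.zeros(n, bool)
        bits[list(medoids)] = True
        assignment = np.full(n, medoids[0])
        return MedoidSolution(bits=bits, assignment=assignment,
                              leader_inertia=inertia, n_clusters=len(medoids))

    def test_merge_with_itself_is_identity(self):
        labels = [f"n{i}" for i in range(5)]
        front = ParetoFront(labels=labels,
                            solutions=[self.make_solution(5, [0, 1], 1.0)])
        merged = merge_fronts([front, front])
        assert merged.objective_set() == front.objective_set()

    def test_dominated_duplicate_k_removed(self):
        labels = [f"n{i}" for i in range(5)]
        worse = ParetoFront(labels, [self.make_solution(5, [0, 1], 1.0)])
        better = ParetoFront(labels, [self.make_solution(5, [2, 3], 0.5)])
        merged = merge_fronts([worse, better])
        assert merged.objective_set() == {(0.5, 2)}

    def test_merged_front_is_a_strict_staircase(self):
        rng = np.random.default_rng(77)
        m1, m2 = random_distance_matrix(12, rng), random_distance_matrix(12, rng)
        front = run_bilevel(m1, m2, EAConfig.desk(rng_seed=4, generations=150,
                                                  independent_runs=3))
        ordered = front.sorted_by_k()
        inertias = [s.leader_inertia for s in ordered]
        assert all(a > b for a, b in zip(inertias, inertias[1:]))

    def test_select_per_k_keeps_best_f_measure(self):
        labels = ["a", "b", "c", "d"]
        ref = ReferenceClasses(classes=[("L", {"a", "b"}), ("R", {"c", "d"})])
        good = MedoidSolution(
            bits=np.array([True, False, True, False]),
            assignment=np.array([0, 0, 2, 2]), leader_inertia=1.0, n_clusters=2)
        bad = MedoidSolution(
            bits=np.array([True, False, False, True]),
            assignment=np.array([0, 3, 0, 3]), leader_inertia=0.9, n_clusters=2)
        front = ParetoFront(labels=labels, solutions=[good, bad])
        picked = select_per_k(front, ref)
        assert set(picked) == {2}
        sol, score = picked[2]
        assert sol is good and score == pytest.approx(1.0)
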