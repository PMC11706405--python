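import numpy as np
import pytest

from neurofit.errors import ErrorVector
from neurofit.optim import (
    ALGORITHMS,
    Candidate,
    OptimizerConfig,
    ParameterSpace,
    Problem,
    ceo,
    cmaes,
    crowding_distance,
    de,
    de_trial,
    fast_non_dominated_sort,
    nelder_mead,
    nsga2,
    pso,
    random_search,
    run_optimizer,
    scalar_problem,
    select_winner,
)
from neurofit.reporting import cumulative_min_curve, final_score


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def space_nd(d, lo=-5.0, hi=5.0):
    return ParameterSpace(tuple(f"x{i}" for i in range(d)), np.full(d, lo), np.full(d, hi))


def brute_force_ranks(F):
    """O(n^2 m) dominance-peeling oracle for non-dominated sorting."""
    n = F.shape[0]
    remaining = set(range(n))
    ranks = np.empty(n, dtype=int)
    rank = 0
    while remaining:
        front = []
        for p in remaining:
            dominated = False
            for q in remaining:
                if q == p:
                    continue
                if np.all(F[q] <= F[p]) and np.any(F[q] < F[p]):
                    dominated = True
                    break
            if not dominated:
                front.append(p)
        for p in front:
            ranks[p] = rank
            remaining.discard(p)
        rank += 1
    return ranks


class TestHarnessInvariants:
    @pytest.mark.parametrize("name", sorted(ALGORITHMS))
    def test_budget_exact_seed_determinism_and_bounds(self, name):
        def make_problem():
            if name == "nsga2":
                return scalar_problem(
                    lambda x: np.array([sphere(x), sphere(x - 1.0)]),
                    space_nd(3),
                    n_objectives=2,
                )
            return scalar_problem(sphere, space_nd(3))

        cfg = OptimizerConfig(name, pop_size=10, n_generations=5, seed=42)
        run1 = run_optimizer(make_problem(), cfg)
        run2 = run_optimizer(make_problem(), cfg)
        assert run1.n_evals == 50
        assert run2.n_evals == 50
        p1 = np.vstack([p for p, _ in run1.eval_log])
        p2 = np.vstack([p for p, _ in run2.eval_log])
        assert np.array_equal(p1, p2)  # bit-identical under the same seed
        assert np.all(p1 >= -5.0) and np.all(p1 <= 5.0)
        curve = cumulative_min_curve(run1)
        assert np.all(np.diff(curve) <= 0.0 + 1e-15)

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError):
            run_optimizer(
                scalar_problem(sphere, space_nd(2)), OptimizerConfig("magic", 10, 5, 0)
            )


class TestRandomSearch:
    def test_mean_best_matches_order_statistic(self):
        # min of n U(0,1) has mean 1/(n+1) and var n/((n+1)^2 (n+2))
        space = ParameterSpace(("x",), np.array([0.0]), np.array([1.0]))
        n = 100
        bests = []
        for seed in range(200):
            run = random_search(
                scalar_problem(lambda x: float(x[0]), space),
                OptimizerConfig("random", pop_size=n, n_generations=1, seed=seed),
            )
            bests.append(final_score(run))
        mean_exp = 1.0 / (n + 1)
        se = np.sqrt(n / ((n + 1) ** 2 * (n + 2)) / 200)
        assert abs(np.mean(bests) - mean_exp) < 3 * se

    def test_budget_one(self):
        run = random_search(
            scalar_problem(sphere, space_nd(2)), OptimizerConfig("random", 1, 1, 0)
        )
        assert run.n_evals == 1


class TestNelderMead:
    def test_converges_on_2d_sphere(self):
        run = nelder_mead(
            scalar_problem(sphere, space_nd(2)), OptimizerConfig("nelder_mead", 100, 5, 1)
        )
        assert run.n_evals == 500
        assert final_score(run) < 1e-8

    def test_constant_function_spends_budget(self):
        run = nelder_mead(
            scalar_problem(lambda x: 7.0, space_nd(2)),
            OptimizerConfig("nelder_mead", 10, 3, 0),
        )
        assert run.n_evals == 30
        assert final_score(run) == 7.0

    def test_boundary_optimum_reached(self):
        # f decreasing in x: minimum at the upper bound
        space = ParameterSpace(("x",), np.array([0.0]), np.array([1.0]))
        run = nelder_mead(
            scalar_problem(lambda x: -float(x[0]), space),
            OptimizerConfig("nelder_mead", 100, 3, 0),
        )
        assert run.best_params[0] == pytest.approx(1.0, abs=1e-6)


class TestCEO:
    def test_sphere_convergence(self):
        ok = 0
        for seed in range(10):
            run = ceo(
                scalar_problem(sphere, space_nd(3)), OptimizerConfig("ceo", 100, 100, seed)
            )
            # < 1e-3 in normalized coordinates -> < 1e-3 * (10 mV span)^2 physical
            if final_score(run) < 1e-3 * 100.0:
                ok += 1
        assert ok >= 9

    def test_operator_ablation_degenerates_to_elites(self):
        cfg = OptimizerConfig(
            "ceo",
            pop_size=8,
            n_generations=10,
            seed=3,
            hyperparams={"mutation_rate": 0.0, "crossover_rate": 0.0},
        )
        prob = scalar_problem(sphere, space_nd(2))
        ceo(prob, cfg)
        params = np.vstack([p for p, _ in prob.eval_log])
        first_gen = {tuple(p) for p in params[:8]}
        last_gen = {tuple(p) for p in params[-8:]}
        assert last_gen <= first_gen  # only copies of existing individuals remain


class TestCMAES:
    def test_sphere_10d_reaches_deep_minimum(self):
        for seed in range(5):
            run = cmaes(
                scalar_problem(sphere, space_nd(10)),
                OptimizerConfig("cmaes", 100, 100, seed),
            )
            assert final_score(run) < 1e-10

    def test_rosenbrock_5d(self):
        from scipy.optimize import rosen

        space = space_nd(5, -2.048, 2.048)
        ok = 0
        for seed in range(5):
            run = cmaes(
                scalar_problem(lambda x: float(rosen(x)), space),
                OptimizerConfig("cmaes", 100, 100, seed),
            )
            if final_score(run) < 1e-6:
                ok += 1
        assert ok >= 4


class TestPSO:
    def test_sphere_convergence(self):
        ok = 0
        for seed in range(10):
            run = pso(
                scalar_problem(sphere, space_nd(3)), OptimizerConfig("pso", 100, 100, seed)
            )
            if final_score(run) < 1e-6:
                ok += 1
        assert ok >= 9

    def test_gbest_curve_non_increasing(self):
        run = pso(scalar_problem(sphere, space_nd(3)), OptimizerConfig("pso", 20, 20, 0))
        curve = cumulative_min_curve(run)
        assert np.all(np.diff(curve) <= 0)


class TestDE:
    def test_sphere_convergence(self):
        ok = 0
        for seed in range(10):
            run = de(
                scalar_problem(sphere, space_nd(3)), OptimizerConfig("de", 100, 100, seed)
            )
            if final_score(run) < 1e-6:
                ok += 1
        assert ok >= 9

    def test_greedy_replacement_keeps_population_best(self):
        npop = 20
        run = de(scalar_problem(sphere, space_nd(3)), OptimizerConfig("de", npop, 20, 0))
        totals = np.array([ev.total for _, ev in run.eval_log]).reshape(-1, npop)
        # one-to-one greedy acceptance: slot fitness is the running minimum
        # of (initial individual, its trials), so the population best after
        # each generation is non-increasing and ends at the overall best
        slot = totals[0].copy()
        pop_best = [slot.min()]
        for trial_fit in totals[1:]:
            slot = np.minimum(slot, trial_fit)
            pop_best.append(slot.min())
        assert all(b2 <= b1 for b1, b2 in zip(pop_best, pop_best[1:]))
        assert pop_best[-1] == final_score(run)

    def test_trial_operator_with_zero_rates(self):
        rng = np.random.default_rng(7)
        pop = np.array(
            [[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9], [0.2, 0.4, 0.6]]
        )
        trial = de_trial(rng, pop, i=0, F=0.0, CR=0.0)
        # CR=0, F=0: trial equals the target except one forced coordinate
        # copied from the base vector
        diff = trial != pop[0]
        assert diff.sum() == 1
        j = int(np.flatnonzero(diff)[0])
        assert trial[j] in pop[1:, j]

    def test_minimum_population(self):
        with pytest.raises(ValueError):
            de(scalar_problem(sphere, space_nd(2)), OptimizerConfig("de", 3, 5, 0))


class TestNSGA2:
    def test_schaffer_pareto_set(self):
        space = ParameterSpace(("x",), np.array([-1.0]), np.array([2.0]))
        prob = scalar_problem(
            lambda x: np.array([x[0] ** 2, (x[0] - 1.0) ** 2]), space, n_objectives=2
        )
        run = nsga2(prob, OptimizerConfig("nsga2", 100, 100, 0))
        xs = np.array([c.params[0] for c in run.final_population])
        assert xs.min() > -0.05 and xs.max() < 1.05

    def test_final_front_mutually_non_dominated(self):
        space = space_nd(3)
        prob = scalar_problem(
            lambda x: np.array([sphere(x), sphere(x - 1.0)]), space, n_objectives=2
        )
        run = nsga2(prob, OptimizerConfig("nsga2", 40, 20, 1))
        F = np.vstack([c.errors.raw for c in run.final_population])
        assert np.all(fast_non_dominated_sort(F) == 0)

    def test_sort_matches_brute_force_on_hand_set(self):
        F = np.array(
            [[1.0, 1.0], [2.0, 0.5], [2.0, 2.0], [0.5, 3.0], [3.0, 3.0], [1.5, 1.5]]
        )
        assert np.array_equal(fast_non_dominated_sort(F), brute_force_ranks(F))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sort_matches_brute_force_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.random((50, 3))
        assert np.array_equal(fast_non_dominated_sort(F), brute_force_ranks(F))

    def test_crowding_boundary_points_infinite(self):
        F = np.array([[0.0, 3.0], [1.0, 2.0], [2.0, 1.0], [3.0, 0.0]])
        d = crowding_distance(F)
        assert np.isinf(d[0]) and np.isinf(d[3])
        assert np.isfinite(d[1]) and np.isfinite(d[2])

    def test_rejects_single_objective_problem(self):
        with pytest.raises(ValueError):
            nsga2(scalar_problem(sphere, space_nd(2)), OptimizerConfig("nsga2", 10, 5, 0))


def _cand(raws, index):
    n = len(raws)
    comps = tuple((f"f{i}", float(r), 1.0 / n, float(r) / n) for i, r in enumerate(raws))
    return Candidate(
        params=np.zeros(1), errors=ErrorVector(comps, sum(r / n for r in raws)), index=index
    )


class TestSelectWinner:
    def test_single_candidate(self):
        c = _cand([1.0, 2.0], 0)
        assert select_winner([c]) is c

    def test_tie_breaks_to_earliest(self):
        a = _cand([1.0, 0.0], 5)
        b = _cand([0.0, 1.0], 2)
        assert select_winner([a, b], weights=[1.0, 1.0]) is b

    def test_weights_select_axis(self):
        cands = [_cand([3.0, 0.0], 0), _cand([2.0, 5.0], 1), _cand([1.0, 9.0], 2)]
        assert select_winner(cands, weights=[1.0, 0.0]) is cands[2]
        assert select_winner(cands, weights=[0.0, 1.0]) is cands[0]

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            select_winner([])
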