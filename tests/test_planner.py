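import numpy as np
import pytest
from scipy.optimize import minimize

from teamperf import (
    Allocation,
    AllocationProblem,
    ScoreTable,
    clairvoyant_payoffs,
    evaluate_policies,
    optimal_allocation,
    payoff,
    run_policy,
)
from teamperf.planner import _pdoc_clip
from teamperf.synth import SyntheticSpec, gen_score_table


def simplex_grid_max(s: np.ndarray, alpha: float, step: float) -> float:
    """Exhaustive simplex grid search for the maximal payoff (n <= 3)."""
    n = len(s)
    k = int(round(1.0 / step))
    if n == 2:
        w1 = np.linspace(0.0, 1.0, k + 1)
        w = np.column_stack([w1, 1.0 - w1])
        return float((w @ s - alpha * (w * w).sum(axis=1)).max())
    assert n == 3
    best = -np.inf
    for i in range(k + 1):
        w1 = i * step
        w2 = np.linspace(0.0, 1.0 - w1, k - i + 1)
        w3 = 1.0 - w1 - w2
        vals = s[0] * w1 + s[1] * w2 + s[2] * w3 - alpha * (w1 * w1 + w2 * w2 + w3 * w3)
        best = max(best, float(vals.max()))
    return best


def slsqp_max(s: np.ndarray, alpha: float) -> float:
    n = len(s)
    res = minimize(
        lambda w: -(s @ w - alpha * w @ w),
        np.full(n, 1.0 / n),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"ftol": 1e-12, "maxiter": 200},
    )
    return -res.fun


class TestPayoff:
    def test_concentrated_allocation(self):
        assert payoff(np.array([1.0, 0.0]), np.array([1.0, 0.0]), 0.2) == pytest.approx(0.8)

    def test_uniform_closed_form(self):
        rng = np.random.default_rng(0)
        for n in (2, 5, 9):
            s = rng.uniform(0, 1, n)
            got = payoff(s, np.full(n, 1 / n), 0.2)
            assert got == pytest.approx(s.mean() - 0.2 / n)

    def test_alpha_zero_is_linear(self):
        s = np.array([0.3, 0.9])
        w = np.array([0.4, 0.6])
        assert payoff(s, w, 0.0) == pytest.approx(s @ w)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            payoff(np.array([1.0, 0.0]), np.array([0.6, 0.6]), 0.2)


class TestOptimalAllocation:
    def test_constant_scores_uniform(self):
        alloc = optimal_allocation(np.full(4, 0.7), 0.2)
        assert alloc.omega == pytest.approx(np.full(4, 0.25))

    def test_interior_hand_case(self):
        alloc = optimal_allocation(np.array([1.0, 0.0]), 1.0)
        assert alloc.omega == pytest.approx([0.75, 0.25])

    def test_support_exclusion_hand_case(self):
        alloc = optimal_allocation(np.array([0.8, 0.6, 0.4]), 0.2)
        assert alloc.omega == pytest.approx([0.75, 0.25, 0.0], abs=1e-12)

    def test_concentrates_when_penalty_weak(self):
        # a clear winner under a weak fairness penalty takes the whole task
        alloc = optimal_allocation(np.array([1.0, 0.0, 0.0, 0.0]), 0.2)
        assert alloc.omega == pytest.approx([1.0, 0.0, 0.0, 0.0])

    def test_alpha_zero_ties_split_uniformly(self):
        alloc = optimal_allocation(np.array([0.9, 0.9, 0.1]), 0.0)
        assert alloc.omega == pytest.approx([0.5, 0.5, 0.0])

    def test_matches_exhaustive_grid_search(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(2, 4))
            s = rng.uniform(0, 1, n)
            alpha = float(rng.uniform(0.05, 1.0))
            ours = payoff(s, optimal_allocation(s, alpha), alpha)
            grid = simplex_grid_max(s, alpha, 1e-3)
            assert ours >= grid - 1e-12
            assert ours - grid < 1e-5

    def test_matches_constrained_optimizer(self):
        rng = np.random.default_rng(32)
        for _ in range(200):
            n = int(rng.integers(2, 5))
            s = rng.uniform(0, 1, n)
            alpha = float(rng.uniform(0.05, 1.0))
            ours = payoff(s, optimal_allocation(s, alpha), alpha)
            assert abs(ours - slsqp_max(s, alpha)) < 1e-5

    def test_always_on_simplex_and_dominant(self):
        rng = np.random.default_rng(33)
        for _ in range(50):
            n = int(rng.integers(2, 8))
            s = rng.uniform(0, 1, n)
            alpha = float(rng.uniform(0.01, 1.0))
            alloc = optimal_allocation(s, alpha)
            assert alloc.omega.sum() == pytest.approx(1.0, abs=1e-9)
            assert (alloc.omega >= -1e-12).all()
            best = payoff(s, alloc, alpha)
            for _ in range(100):
                raw = rng.uniform(0, 1, n)
                other = raw / raw.sum()
                assert best >= payoff(s, other, alpha) - 1e-9

    def test_monotone_in_own_score(self):
        rng = np.random.default_rng(34)
        for _ in range(30):
            n = 4
            s = rng.uniform(0, 1, n)
            alpha = float(rng.uniform(0.05, 0.5))
            i = int(rng.integers(n))
            before = optimal_allocation(s, alpha).omega[i]
            s2 = s.copy()
            s2[i] += rng.uniform(0.05, 0.5)
            after = optimal_allocation(s2, alpha).omega[i]
            assert after >= before - 1e-9


class TestPolicies:
    def _problem(self, seed=42, n_teams=8, with_train=True):
        table = gen_score_table(SyntheticSpec(n_teams=n_teams + 14), seed)
        hist = None
        if with_train:
            hist = ScoreTable(team_ids=table.team_ids[n_teams:], task_ids=table.task_ids,
                              scores=table.scores[n_teams:])
        return AllocationProblem(scores=table.scores[:n_teams], hist_train=hist, alpha=0.2)

    def test_uniform_policy_definition(self):
        problem = self._problem(with_train=False, n_teams=5)
        run = run_policy("uniform", problem)
        assert np.allclose(run.omegas, 1.0 / 5)

    def test_pdoc_clip_worked_examples(self):
        observed = np.full((3, 4), 0.5)  # mean_k = 0.5 for every team
        raw = np.array([0.9, 0.2, 0.5])
        clipped = _pdoc_clip(raw, observed, 0.3)
        assert clipped == pytest.approx([0.65, 0.35, 0.5])

    def test_naive_concentrates_on_clear_winner(self):
        # s(1) = (1, 0, 0, 0), alpha = 0.2: the optimum puts all work on
        # team 1 (verified against the constrained-optimizer oracle)
        scores = np.array([[1.0, 0.5], [0.0, 0.5], [0.0, 0.5], [0.0, 0.5]])
        problem = AllocationProblem(scores=scores, alpha=0.2)
        run = run_policy("naive", problem)
        expected_payoff = slsqp_max(scores[:, 0], 0.2)
        got = payoff(scores[:, 0], Allocation(run.omegas[1]), 0.2)
        assert run.omegas[1] == pytest.approx([1.0, 0.0, 0.0, 0.0], abs=1e-9)
        assert abs(got - expected_payoff) < 1e-6

    def test_first_task_allocations_uniform(self):
        problem = self._problem(with_train=False, n_teams=6)
        for name in ("naive", "mean", "least_squares"):
            run = run_policy(name, problem)
            assert np.allclose(run.omegas[0], 1.0 / 6)

    def test_clairvoyant_bounds_every_policy(self):
        problem = self._problem(with_train=False, n_teams=8)
        bound = clairvoyant_payoffs(problem)
        for name in ("uniform", "oracle", "naive", "mean", "least_squares"):
            run = run_policy(name, problem)
            assert (run.payoffs <= bound + 1e-9).all()
            for t in range(problem.n_tasks):
                omega = run.omegas[t]
                assert omega.sum() == pytest.approx(1.0, abs=1e-9)
                assert (omega >= -1e-12).all()

    def test_pdoc_estimates_respect_clip_interval(self):
        problem = self._problem()
        run = run_policy("pdoc", problem, seed=1)
        eps = 0.3
        for t in range(1, problem.n_tasks):  # tasks with at least 1 observation
            means = problem.scores[:, :t].mean(axis=1)
            est = run.estimates[t]
            assert (est >= (1 - eps) * means - 1e-9).all()
            assert (est <= (1 + eps) * means + 1e-9).all()

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            run_policy("greedy", self._problem(with_train=False))

    def test_pd_requires_training_data(self):
        with pytest.raises(ValueError, match="training"):
            run_policy("pd", self._problem(with_train=False))


class TestEvaluatePolicies:
    def test_oracle_relative_payoff_is_one(self):
        table = gen_score_table(SyntheticSpec(n_teams=20), 3)
        report = evaluate_policies(table, policies=["oracle", "uniform"], repeats=5, seed=2)
        assert report.summary.loc["oracle", "relative_payoff"] == pytest.approx(1.0)

    def test_naive_beats_uniform_under_persistent_quality(self):
        # strong persistent team quality: yesterday's score is informative
        spec = SyntheticSpec(n_teams=20, noise_sd=0.02, trend_coupling=0.0,
                             quality_low=0.1, quality_high=0.9)
        table = gen_score_table(spec, 5)
        report = evaluate_policies(table, policies=["naive", "uniform"], repeats=20, seed=4)
        assert (report.summary.loc["naive", "cumulative_payoff"]
                >= report.summary.loc["uniform", "cumulative_payoff"])

    def test_too_few_managed_teams_rejected(self):
        table = gen_score_table(SyntheticSpec(n_teams=5), 0)
        with pytest.raises(ValueError):
            evaluate_policies(table, policies=["uniform"], train_frac=0.9, repeats=1)
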