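"""Online workload distribution across teams on the probability simplex.

A manager sequentially assigns shares of each task t to n teams.  The share
vector omega(t) lives on the simplex (non-negative, sums to 1) and earns

    R(t) = s(t)' omega(t) - alpha * ||omega(t)||^2

where s(t) are the teams' realized scores and alpha (default 0.2) trades off
exploiting the best-scoring teams against a quadratic fairness/exploration
penalty that favors spreading work.  Given a score estimate s_est, the
optimal omega maximizes a strictly concave quadratic over the simplex; the
maximizer has the water-filling form omega_i = max(0, (s_i - mu) / (2 alpha))
with mu the Lagrange multiplier of the sum constraint, found exactly by a
support scan — equivalently, the Euclidean projection of s_est / (2 alpha)
onto the simplex.

Policies differ only in how they estimate s_est: uniform assignment, a
non-causal mean oracle, naive / observed-mean / least-squares / ARMA
extrapolation of each team's own series, and two model-based policies (pd,
pdoc) that fit the elastic-net dynamics model on training teams and apply it
to the managed teams, pdoc additionally clipping estimates to within a
+-epsilon fraction (default 0.3) of each team's observed mean to guard the
allocation against outlier predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import dynamics_feature_table, dynamics_features
from .forecast import forecast
from .io import ScoreTable
from .model import ElasticNetModel, select_model, small_lambda_grid

__all__ = [
    "SIMPLEX_TOL",
    "POLICIES",
    "AllocationProblem",
    "Allocation",
    "PolicyRun",
    "PolicyReport",
    "payoff",
    "optimal_allocation",
    "run_policy",
    "clairvoyant_payoffs",
    "evaluate_policies",
]

SIMPLEX_TOL = 1e-9
POLICIES = ("uniform", "oracle", "naive", "mean", "least_squares", "arma", "pd", "pdoc")

#: Model-based policies start once three scores are observed (the dynamics
#: features need a prefix of length >= 3), i.e. from task 4.
_MIN_MODEL_TASK = 4


@dataclass(frozen=True)
class Allocation:
    """A workload share vector on the probability simplex."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.omega, dtype=float)
        object.__setattr__(self, "omega", w)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("omega must be a non-empty vector")
        if (w < -SIMPLEX_TOL).any() or abs(w.sum() - 1.0) > SIMPLEX_TOL:
            raise ValueError("omega must be non-negative and sum to 1")


@dataclass
class AllocationProblem:
    """The manager's data: managed teams' scores and (optional) training data.

    ``scores`` is the full n_teams x m matrix of the managed teams (revealed
    one column per step); ``hist_train`` is the complete score table of the
    previously-managed training teams, needed only by the model-based
    policies.
    """

    scores: np.ndarray  # managed teams x tasks, all finite, in [0, 1]
    hist_train: ScoreTable | None = None
    alpha: float = 0.2

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] < 2:
            raise ValueError("need a 2-D score matrix with at least 2 managed teams")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("managed team scores must be complete")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    @property
    def n_teams(self) -> int:
        return self.scores.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.scores.shape[1]


@dataclass
class PolicyRun:
    """Trace of one policy over one task sequence."""

    policy: str
    omegas: np.ndarray  # tasks x teams
    estimates: np.ndarray  # tasks x teams score estimates (NaN for uniform)
    payoffs: np.ndarray  # per-task payoff R(t)
    seed: int = 0

    @property
    def cumulative_payoff(self) -> float:
        return float(self.payoffs.sum())


def payoff(s: np.ndarray, allocation: Allocation | np.ndarray, alpha: float) -> float:
    """R = s' omega - alpha ||omega||^2; omega must be on the simplex."""
    omega = allocation.omega if isinstance(allocation, Allocation) else Allocation(np.asarray(allocation)).omega
    sv = np.asarray(s, dtype=float)
    if sv.shape != omega.shape:
        raise ValueError("score and allocation lengths differ")
    return float(sv @ omega - alpha * omega @ omega)


def optimal_allocation(s_est: np.ndarray, alpha: float) -> Allocation:
    """Exact maximizer of s' omega - alpha ||omega||^2 over the simplex.

    For alpha > 0 the problem is strictly concave with the unique
    water-filling solution omega_i = max(0, (s_i - mu) / (2 alpha)); the
    support is found by scanning the sorted scores.  For alpha = 0 the
    problem is linear and ties on the maximal score are split uniformly.
    """
    s = np.asarray(s_est, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("score estimates must be finite")
    n = s.size
    if alpha == 0.0:
        best = s == s.max()
        return Allocation(best / best.sum())
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    v = s / (2.0 * alpha)
    u = np.sort(v)[::-1]
    cumsum = np.cumsum(u)
    k = np.arange(1, n + 1)
    support = u - (cumsum - 1.0) / k > 0
    k_star = int(k[support][-1])
    mu_scaled = (cumsum[k_star - 1] - 1.0) / k_star  # = mu / (2 alpha)
    return Allocation(np.maximum(v - mu_scaled, 0.0))


def _pdoc_clip(estimates: np.ndarray, observed: np.ndarray, epsilon: float) -> np.ndarray:
    """Clip estimates into [(1-eps)*mean_k, (1+eps)*mean_k] per team, where
    mean_k is the mean of team k's observed scores so far."""
    means = observed.mean(axis=1)
    lo, hi = (1.0 - epsilon) * means, (1.0 + epsilon) * means
    return np.minimum(np.maximum(estimates, lo), hi)


def _train_dynamics_models(
    hist_train: ScoreTable,
    n_tasks: int,
    seed: int,
    lambda_grid,
) -> dict[int, ElasticNetModel]:
    """One elastic-net dynamics model per target task t >= 4, trained on the
    training teams' prefixes (features from tasks < t, target task t)."""
    models: dict[int, ElasticNetModel] = {}
    for t in range(_MIN_MODEL_TASK, n_tasks + 1):
        feats = dynamics_feature_table(hist_train, t)
        # drop features undefined for some team (e.g. skewness of a constant
        # prefix) rather than dropping teams
        feats = feats.dropna(axis=1, how="any")
        target = pd.Series(hist_train.scores[:, t - 1], index=hist_train.team_ids)
        ok = target.notna()
        X = feats.loc[ok]
        if len(X) < 10 or X.shape[1] == 0:
            continue
        models[t] = select_model(X, target.loc[ok].to_numpy(), lambda_grid=lambda_grid,
                                 seed=seed)
    return models


def run_policy(
    name: str,
    problem: AllocationProblem,
    seed: int = 0,
    epsilon: float = 0.3,
    lambda_grid=None,
    models: Mapping[int, ElasticNetModel] | None = None,
) -> PolicyRun:
    """Execute one workload-distribution policy over the task sequence.

    Score estimates come from the policy's predictor; the allocation is the
    exact optimum for those estimates (except the uniform policy).  Policies
    with insufficient history fall back to the observed-mean estimate, which
    on the first task is the constant prior 0.5 and hence a uniform
    allocation.  ``pd``/``pdoc`` require ``problem.hist_train``.
    """
    if name not in POLICIES:
        raise ValueError(f"unknown policy {name!r}; choose from {POLICIES}")
    n, m = problem.n_teams, problem.n_tasks
    alpha = problem.alpha
    if name in ("pd", "pdoc") and models is None:
        if problem.hist_train is None:
            raise ValueError(f"policy {name!r} needs training data (hist_train)")
        if lambda_grid is None:
            lambda_grid = small_lambda_grid()
        models = _train_dynamics_models(problem.hist_train, m, seed, lambda_grid)
    models = models or {}

    omegas = np.zeros((m, n))
    estimates = np.full((m, n), np.nan)
    payoffs = np.zeros(m)
    for t in range(1, m + 1):
        observed = problem.scores[:, : t - 1]
        if name == "uniform":
            alloc = Allocation(np.full(n, 1.0 / n))
        else:
            est = _estimate_scores(name, problem, observed, t, models, epsilon)
            estimates[t - 1] = est
            alloc = optimal_allocation(est, alpha)
        omegas[t - 1] = alloc.omega
        payoffs[t - 1] = payoff(problem.scores[:, t - 1], alloc, alpha)
    return PolicyRun(policy=name, omegas=omegas, estimates=estimates,
                     payoffs=payoffs, seed=seed)


def _estimate_scores(
    name: str,
    problem: AllocationProblem,
    observed: np.ndarray,
    t: int,
    models: Mapping[int, ElasticNetModel],
    epsilon: float,
) -> np.ndarray:
    n = problem.n_teams
    if name == "oracle":
        return problem.scores.mean(axis=1)
    if name in ("naive", "mean", "least_squares", "arma"):
        method = {"naive": "naive", "mean": "observed_mean",
                  "least_squares": "least_squares", "arma": "arma"}[name]
        return np.array([forecast(method, observed[i], t) for i in range(n)])
    # pd / pdoc: dynamics model for task t applied to the managed prefixes,
    # falling back to the observed mean before task 4 or without a model.
    if t < _MIN_MODEL_TASK or t not in models:
        est = np.array([forecast("observed_mean", observed[i], t) for i in range(n)])
    else:
        model = models[t]
        feats = pd.DataFrame([dynamics_features(observed[i]) for i in range(n)])
        feats = feats[model.coefficients.index]
        if model.feature_means is not None:
            feats = feats.fillna(model.feature_means)  # undefined -> average
        est = np.clip(model.predict(feats), 0.0, 1.0)
    if name == "pdoc" and observed.shape[1] >= 1:
        est = _pdoc_clip(est, observed, epsilon)
    return est


def clairvoyant_payoffs(problem: AllocationProblem) -> np.ndarray:
    """Per-task payoff of the clairvoyant allocation that sees the true s(t)
    before choosing omega(t); an upper bound for every policy at every step."""
    return np.array(
        [
            payoff(problem.scores[:, t], optimal_allocation(problem.scores[:, t], problem.alpha),
                   problem.alpha)
            for t in range(problem.n_tasks)
        ]
    )


@dataclass
class PolicyReport:
    """Mean results of repeated split evaluation.

    ``summary`` has one row per policy with the mean cumulative payoff over
    repeats and its ratio to the oracle baseline's; ``mean_allocations`` maps
    policy -> (tasks x teams) allocation matrix averaged over repeats (teams
    ordered by their position in the managed split).
    """

    summary: pd.DataFrame
    mean_allocations: dict[str, np.ndarray]
    repeats: int
    train_frac: float
    alpha: float
    seed: int


def evaluate_policies(
    table: ScoreTable,
    policies: Sequence[str] = POLICIES,
    train_frac: float = 0.75,
    repeats: int = 100,
    alpha: float = 0.2,
    seed: int = 0,
    epsilon: float = 0.3,
    lambda_grid=None,
) -> PolicyReport:
    """Evaluate policies over repeated random train/managed splits of teams.

    Each repeat draws a seeded random split (default 75% training teams whose
    full histories feed the model-based policies, 25% managed teams the
    policies allocate work to), runs every policy on the managed set, and
    accumulates cumulative payoffs.  The report scales each policy's mean
    cumulative payoff by the oracle baseline's (the oracle is always run).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    scores = table.scores
    if not np.all(np.isfinite(scores)):
        raise ValueError("policy evaluation needs a complete score table")
    n_teams = table.n_teams
    n_train = int(round(train_frac * n_teams))
    if n_teams - n_train < 2:
        raise ValueError("fewer than 2 managed teams; lower train_frac")

    run_names = list(dict.fromkeys(list(policies) + ["oracle"]))
    totals = {p: 0.0 for p in run_names}
    alloc_sums = {p: np.zeros((table.n_tasks, n_teams - n_train)) for p in run_names}
    rng = np.random.default_rng(seed)
    for rep in range(repeats):
        perm = rng.permutation(n_teams)
        train_idx, managed_idx = perm[:n_train], perm[n_train:]
        hist_train = ScoreTable(
            team_ids=[table.team_ids[i] for i in train_idx],
            task_ids=table.task_ids,
            scores=scores[train_idx],
        )
        problem = AllocationProblem(scores=scores[managed_idx], hist_train=hist_train,
                                    alpha=alpha)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        shared_models = None
        if "pd" in run_names or "pdoc" in run_names:
            shared_models = _train_dynamics_models(
                hist_train, table.n_tasks, rep_seed,
                lambda_grid if lambda_grid is not None else small_lambda_grid())
        for p in run_names:
            run = run_policy(p, problem, seed=rep_seed, epsilon=epsilon,
                             lambda_grid=lambda_grid,
                             models=shared_models if p in ("pd", "pdoc") else None)
            totals[p] += run.cumulative_payoff
            alloc_sums[p] += run.omegas
    means = {p: totals[p] / repeats for p in run_names}
    oracle_mean = means["oracle"]
    summary = pd.DataFrame(
        {
            "cumulative_payoff": [means[p] for p in run_names],
            "relative_payoff": [means[p] / oracle_mean for p in run_names],
        },
        index=pd.Index(run_names, name="policy"),
    )
    return PolicyReport(
        summary=summary,
        mean_allocations={p: alloc_sums[p] / repeats for p in run_names},
        repeats=repeats, train_frac=train_frac, alpha=alpha, seed=seed,
    )
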