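"""Native implementations of the benchmarked search algorithms.

All algorithms minimize over a bounded box. Internally every algorithm works
in normalized [0, 1]^d coordinates with an affine map to the physical
bounds, so hyperparameters with a length scale (mutation sigma, CMA-ES
initial step size, PSO velocity clamp) are stated in normalized units and
behave sensibly when parameters span orders of magnitude.

The shared contract:

* every optimizer takes a :class:`Problem` and an :class:`OptimizerConfig`
  and returns a :class:`~neurofit.reporting.RunResult`;
* candidates are submitted for evaluation a whole generation at a time
  through a single batch entry point (results come back in submission
  order), so an objective may vectorize or parallelize internally;
* the evaluation budget ``pop_size * n_generations`` is respected exactly,
  unless an explicit ``target_error`` hyperparameter requests stopping at
  the end of the first generation whose cumulative minimum reaches it;
* all randomness comes from one generator seeded by ``config.seed``, making
  runs bit-reproducible;
* a failed simulation reports the sentinel error 1e9 instead of aborting
  the run.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ErrorVector
from .reporting import RunResult, build_run_result

__all__ = [
    "ParameterSpace",
    "Problem",
    "Candidate",
    "OptimizerConfig",
    "FAILURE_SENTINEL",
    "random_search",
    "nelder_mead",
    "ceo",
    "cmaes",
    "pso",
    "de",
    "nsga2",
    "select_winner",
    "run_optimizer",
    "ALGORITHMS",
    "fast_non_dominated_sort",
    "crowding_distance",
    "de_trial",
    "scalar_problem",
]

FAILURE_SENTINEL = 1e9


@dataclass(frozen=True)
class ParameterSpace:
    """Named box-constrained parameter space."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "names", tuple(self.names))
        if lower.size != upper.size or lower.size != len(self.names):
            raise ValueError("names, lower, upper must have equal length >= 1")
        if lower.size < 1 or not np.all(lower < upper):
            raise ValueError("need lower < upper elementwise")

    @property
    def dim(self) -> int:
        return self.lower.size

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        """Map normalized [0,1] coordinates to physical values."""
        return self.lower + np.asarray(u) * (self.upper - self.lower)

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x) - self.lower) / (self.upper - self.lower)


@dataclass(frozen=True)
class Candidate:
    params: np.ndarray
    errors: ErrorVector
    index: int = 0  # evaluation order, used for deterministic tie-breaks


class Problem:
    """A bounded objective with an append-only evaluation log.

    ``objective`` maps a (n, d) batch of physical parameter vectors to a
    list of n :class:`ErrorVector`. ``n_objectives`` > 1 marks a
    multi-objective problem whose per-component raw errors are exposed to
    multi-objective algorithms; single-objective algorithms always minimize
    ``ErrorVector.total``.
    """

    def __init__(
        self,
        space: ParameterSpace,
        objective: Callable[[np.ndarray], list[ErrorVector]],
        n_objectives: int = 1,
    ) -> None:
        self.space = space
        self.objective = objective
        self.n_objectives = n_objectives
        self.eval_log: list[tuple[np.ndarray, ErrorVector]] = []

    @property
    def eval_counter(self) -> int:
        return len(self.eval_log)

    def evaluate_unit_batch(self, U: np.ndarray) -> list[ErrorVector]:
        """Evaluate a batch given in normalized coordinates (clipped to the box)."""
        U = np.clip(np.asarray(U, dtype=float).reshape(-1, self.space.dim), 0.0, 1.0)
        X = self.space.from_unit(U)
        evs = self.objective(X)
        if len(evs) != X.shape[0]:
            raise RuntimeError("objective returned wrong batch size")
        for x, ev in zip(X, evs):
            self.eval_log.append((x.copy(), ev))
        return evs

    def totals(self, evs: Sequence[ErrorVector]) -> np.ndarray:
        return np.array([ev.total for ev in evs])

    def objective_matrix(self, evs: Sequence[ErrorVector]) -> np.ndarray:
        if self.n_objectives == 1:
            return self.totals(evs)[:, None]
        return np.vstack([ev.raw for ev in evs])


@dataclass(frozen=True)
class OptimizerConfig:
    algorithm: str
    pop_size: int = 100
    n_generations: int = 100
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    @property
    def budget(self) -> int:
        return self.pop_size * self.n_generations


def scalar_problem(
    f: Callable[[np.ndarray], float],
    space: ParameterSpace,
    n_objectives: int = 1,
) -> Problem:
    """Wrap a plain scalar (or vector) function as a Problem; used by tests
    and the classic optimization test functions."""

    def objective(X: np.ndarray) -> list[ErrorVector]:
        out = []
        for x in X:
            val = f(x)
            if np.ndim(val) == 0:
                comps = (("f", float(val), 1.0, float(val)),)
                total = float(val)
            else:
                val = np.asarray(val, dtype=float)
                w = 1.0 / val.size
                comps = tuple(
                    (f"f{i}", float(v), w, float(v) * w) for i, v in enumerate(val)
                )
                total = float(np.sum(val) * w)
            out.append(ErrorVector(components=comps, total=total))
        return out

    return Problem(space, objective, n_objectives=n_objectives)


def _hit_target(evs: Sequence[ErrorVector], target: float | None) -> bool:
    return target is not None and min(ev.total for ev in evs) <= target


def _finish(
    problem: Problem,
    config: OptimizerConfig,
    started: float,
    final_population: list[Candidate] | None = None,
) -> RunResult:
    return build_run_result(
        benchmark_id=config.hyperparams.get("benchmark_id", ""),
        algorithm=config.algorithm,
        seed=config.seed,
        space=problem.space,
        hyperparams=dict(config.hyperparams),
        pop_size=config.pop_size,
        eval_log=problem.eval_log,
        started=started,
        final_population=final_population,
    )


# ---------------------------------------------------------------------------
# Random search


def random_search(problem: Problem, config: OptimizerConfig) -> RunResult:
    """Uniform i.i.d. sampling over the box — the baseline method."""
    started = time.time()
    rng = np.random.default_rng(config.seed)
    target = config.hyperparams.get("target_error")
    d = problem.space.dim
    for _ in range(config.n_generations):
        evs = problem.evaluate_unit_batch(rng.random((config.pop_size, d)))
        if _hit_target(evs, target):
            break
    return _finish(problem, config, started)


# ---------------------------------------------------------------------------
# Nelder-Mead simplex with uniform restarts


def nelder_mead(problem: Problem, config: OptimizerConfig) -> RunResult:
    """Reflection/expansion/contraction/shrink simplex search.

    Coefficients (alpha, gamma, rho, sigma) = (1, 2, 0.5, 0.5). Proposals are
    clipped to the box. When the simplex collapses (spread below 1e-12 in
    normalized coordinates) the search restarts from a fresh uniform point,
    until the evaluation budget is spent.
    """
    started = time.time()
    rng = np.random.default_rng(config.seed)
    target = config.hyperparams.get("target_error")
    d = problem.space.dim
    budget = config.budget
    alpha, gamma, rho, sig = 1.0, 2.0, 0.5, 0.5
    step = float(config.hyperparams.get("init_step", 0.1))

    def f(u: np.ndarray) -> float:
        ev = problem.evaluate_unit_batch(u[None, :])[0]
        return ev.total

    best_seen = np.inf
    while problem.eval_counter < budget:
        if target is not None and best_seen <= target:
            break
        x0 = rng.random(d)
        verts = [np.clip(x0, 0, 1)]
        for i in range(d):
            v = x0.copy()
            v[i] = v[i] + step if v[i] + step <= 1 else v[i] - step
            verts.append(np.clip(v, 0, 1))
        fv = []
        for v in verts:
            if problem.eval_counter >= budget:
                break
            fv.append(f(v))
        if len(fv) < len(verts):
            break
        verts = np.array(verts)
        fv = np.array(fv)
        best_seen = min(best_seen, fv.min())

        while problem.eval_counter < budget:
            order = np.argsort(fv, kind="stable")
            verts, fv = verts[order], fv[order]
            if np.max(np.abs(verts - verts[0])) < 1e-12 or (
                target is not None and best_seen <= target
            ):
                break
            centroid = verts[:-1].mean(axis=0)
            xr = np.clip(centroid + alpha * (centroid - verts[-1]), 0, 1)
            fr = f(xr)
            best_seen = min(best_seen, fr)
            if fr < fv[0] and problem.eval_counter < budget:
                xe = np.clip(centroid + gamma * (centroid - verts[-1]), 0, 1)
                fe = f(xe)
                best_seen = min(best_seen, fe)
                if fe < fr:
                    verts[-1], fv[-1] = xe, fe
                else:
                    verts[-1], fv[-1] = xr, fr
            elif fr < fv[-2]:
                verts[-1], fv[-1] = xr, fr
            elif problem.eval_counter < budget:
                xc = np.clip(centroid + rho * (verts[-1] - centroid), 0, 1)
                fc = f(xc)
                best_seen = min(best_seen, fc)
                if fc < fv[-1]:
                    verts[-1], fv[-1] = xc, fc
                else:  # shrink toward the best vertex
                    for i in range(1, len(verts)):
                        if problem.eval_counter >= budget:
                            break
                        verts[i] = verts[0] + sig * (verts[i] - verts[0])
                        fv[i] = f(verts[i])
                        best_seen = min(best_seen, fv[i])
    return _finish(problem, config, started)


# ---------------------------------------------------------------------------
# Custom evolutionary optimization (tournament / blend crossover / Gaussian
# mutation / strong elitism)


def _tournament(rng, totals: np.ndarray, k: int = 2) -> int:
    idx = rng.integers(0, totals.size, size=k)
    return int(idx[np.argmin(totals[idx])])


def ceo(problem: Problem, config: OptimizerConfig) -> RunResult:
    """Generational evolutionary algorithm with blend crossover and Gaussian
    mutation.

    Defaults follow the benchmarked configuration: binary-tournament parent
    selection, blend crossover (alpha 0.1) applied to every parent pair,
    per-gene Gaussian mutation with probability 0.25 and sigma 0.5 (both in
    normalized coordinates), and elitism preserving the best half of the
    population between generations.
    """
    started = time.time()
    rng = np.random.default_rng(config.seed)
    hp = config.hyperparams
    target = hp.get("target_error")
    mut_rate = float(hp.get("mutation_rate", 0.25))
    mut_sigma = float(hp.get("mutation_sigma", 0.5))
    cx_alpha = float(hp.get("crossover_alpha", 0.1))
    cx_rate = float(hp.get("crossover_rate", 1.0))
    n_elites = int(hp.get("n_elites", config.pop_size // 2))
    d = problem.space.dim
    pop = rng.random((config.pop_size, d))
    evs = problem.evaluate_unit_batch(pop)
    totals = problem.totals(evs)
    for _ in range(config.n_generations - 1):
        if _hit_target(evs, target):
            break
        children = np.empty_like(pop)
        for i in range(0, config.pop_size, 2):
            p1 = pop[_tournament(rng, totals)]
            p2 = pop[_tournament(rng, totals)]
            if rng.random() < cx_rate:
                lo = np.minimum(p1, p2)
                hi = np.maximum(p1, p2)
                spread = hi - lo
                c1 = rng.uniform(lo - cx_alpha * spread, hi + cx_alpha * spread)
                c2 = rng.uniform(lo - cx_alpha * spread, hi + cx_alpha * spread)
            else:
                c1, c2 = p1.copy(), p2.copy()
            children[i] = c1
            if i + 1 < config.pop_size:
                children[i + 1] = c2
        mutate = rng.random(children.shape) < mut_rate
        children = np.where(
            mutate, children + rng.normal(0.0, mut_sigma, children.shape), children
        )
        children = np.clip(children, 0, 1)
        child_evs = problem.evaluate_unit_batch(children)
        child_totals = problem.totals(child_evs)
        # survivors: best `n_elites` parents plus the best children
        elite_idx = np.argsort(totals, kind="stable")[:n_elites]
        child_idx = np.argsort(child_totals, kind="stable")[: config.pop_size - n_elites]
        pop = np.vstack([pop[elite_idx], children[child_idx]])
        totals = np.concatenate([totals[elite_idx], child_totals[child_idx]])
        evs = child_evs
    return _finish(problem, config, started)


# ---------------------------------------------------------------------------
# CMA-ES


def cmaes(problem: Problem, config: OptimizerConfig) -> RunResult:
    """Covariance Matrix Adaptation Evolution Strategy.

    The standard (mu/mu_w, lambda) formulation: weighted recombination of
    the best mu = lambda/2 samples, rank-one and rank-mu covariance updates,
    and cumulative step-size adaptation. Sampling happens in normalized
    coordinates with the initial mean at the box center and initial sigma
    0.3; out-of-box samples are resampled a few times and then clipped. If
    the covariance loses positive-definiteness (or its conditioning
    degrades), the strategy restarts with an inflated step size while
    preserving the evaluation budget.
    """
    started = time.time()
    rng = np.random.default_rng(config.seed)
    hp = config.hyperparams
    target = hp.get("target_error")
    lam = config.pop_size
    n = problem.space.dim
    sigma0 = float(hp.get("sigma0", 0.3))
    resample_cap = int(hp.get("resample_cap", 10))

    mu = lam // 2
    w = np.log((lam + 1) / 2.0) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)
    cs = (mueff + 2) / (n + mueff + 5)
    ds = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    def init_state():
        return (
            np.eye(n),  # C
            np.zeros(n),  # p_sigma
            np.zeros(n),  # p_c
            sigma0,
        )

    m = np.full(n, 0.5)
    C, ps, pc, sigma = init_state()
    gen = 0
    while gen < config.n_generations:
        try:
            evals_D, B = np.linalg.eigh(C)
        except np.linalg.LinAlgError:
            C, ps, pc, sigma = init_state()
            sigma = min(2 * sigma0, 1.0)
            evals_D, B = np.linalg.eigh(C)
        if evals_D.min() <= 0 or evals_D.max() / max(evals_D.min(), 1e-300) > 1e14:
            C, ps, pc, sigma = init_state()
            sigma = min(2 * sigma0, 1.0)
            evals_D, B = np.linalg.eigh(C)
        D = np.sqrt(evals_D)
        BD = B * D  # C^{1/2}
        inv_sqrt_C = (B / D) @ B.T

        X = np.empty((lam, n))
        for k in range(lam):
            x = m + sigma * (BD @ rng.standard_normal(n))
            tries = 0
            while (np.any(x < 0) or np.any(x > 1)) and tries < resample_cap:
                x = m + sigma * (BD @ rng.standard_normal(n))
                tries += 1
            X[k] = np.clip(x, 0, 1)

        evs = problem.evaluate_unit_batch(X)
        totals = problem.totals(evs)
        order = np.argsort(totals, kind="stable")
        Xs = X[order[:mu]]
        ys = (Xs - m) / sigma
        m_new = w @ Xs
        delta = (m_new - m) / sigma

        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (inv_sqrt_C @ delta)
        hsig = float(
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * (gen + 1))) / chi_n
            < 1.4 + 2 / (n + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * delta
        rank_mu = (ys.T * w) @ ys
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        C = (C + C.T) / 2
        sigma *= np.exp((cs / ds) * (np.linalg.norm(ps) / chi_n - 1))
        if not (np.isfinite(sigma) and np.all(np.isfinite(C)) and np.all(np.isfinite(m_new))):
            C, ps, pc, sigma = init_state()
            sigma = min(2 * sigma0, 1.0)
        else:
            m = m_new
        sigma = float(min(sigma, 1.0))
        gen += 1
        if _hit_target(evs, target):
            break
    return _finish(problem, config, started)


# ---------------------------------------------------------------------------
# Particle swarm (generational, constriction defaults)


def pso(problem: Problem, config: OptimizerConfig) -> RunResult:
    """Generational particle swarm with constriction-type defaults.

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x), then x <- x + v, with
    omega = 0.7298 and c1 = c2 = 1.49618. All particles in a generation are
    updated from the same gbest snapshot; velocities are clamped to half the
    (normalized) box width and positions are clipped to the box.
    """
    started = time.time()
    rng = np.random.default_rng(config.seed)
    hp = config.hyperparams
    target = hp.get("target_error")
    omega = float(hp.get("omega", 0.7298))
    c1 = float(hp.get("c1", 1.49618))
    c2 = float(hp.get("c2", 1.49618))
    vmax = float(hp.get("vmax", 0.5))
    d = problem.space.dim
    npart = config.pop_size

    x = rng.random((npart, d))
    v = np.zeros((npart, d))
    evs = problem.evaluate_unit_batch(x)
    fit = problem.totals(evs)
    pbest, pbest_f = x.copy(), fit.copy()
    g = int(np.argmin(fit))
    gbest, gbest_f = x[g].copy(), float(fit[g])
    for _ in range(config.n_generations - 1):
        if target is not None and gbest_f <= target:
            break
        r1 = rng.random((npart, d))
        r2 = rng.random((npart, d))
        v = omega * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest - x)
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, 0, 1)
        evs = problem.evaluate_unit_batch(x)
        fit = problem.totals(evs)
        improved = fit < pbest_f
        pbest[improved] = x[improved]
        pbest_f[improved] = fit[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    return _finish(problem, config, started)


# ---------------------------------------------------------------------------
# Differential evolution (DE/rand/1/bin)


def de_trial(
    rng: np.random.Generator,
    pop: np.ndarray,
    i: int,
    F: float,
    CR: float,
) -> np.ndarray:
    """Build one DE/rand/1/bin trial vector for target index i."""
    npop = pop.shape[0]
    choices = [j for j in range(npop) if j != i]
    r1, r2, r3 = rng.choice(choices, size=3, replace=False)
    mutant = pop[r1] + F * (pop[r2] - pop[r3])
    d = pop.shape[1]
    cross = rng.random(d) < CR
    cross[rng.integers(0, d)] = True  # forced coordinate
    return np.clip(np.where(cross, mutant, pop[i]), 0, 1)


def de(problem: Problem, config: OptimizerConfig) -> RunResult:
    """DE/rand/1/bin with F = 0.8, CR = 0.9 and greedy one-to-one replacement."""
    if config.pop_size < 4:
        raise ValueError("DE needs a population of at least 4")
    started = time.time()
    rng = np.random.default_rng(config.seed)
    hp = config.hyperparams
    target = hp.get("target_error")
    F = float(hp.get("F", 0.8))
    CR = float(hp.get("CR", 0.9))
    d = problem.space.dim

    pop = rng.random((config.pop_size, d))
    evs = problem.evaluate_unit_batch(pop)
    fit = problem.totals(evs)
    for _ in range(config.n_generations - 1):
        if target is not None and fit.min() <= target:
            break
        trials = np.vstack(
            [de_trial(rng, pop, i, F, CR) for i in range(config.pop_size)]
        )
        tevs = problem.evaluate_unit_batch(trials)
        tfit = problem.totals(tevs)
        better = tfit <= fit
        pop[better] = trials[better]
        fit[better] = tfit[better]
    return _finish(problem, config, started)


# ---------------------------------------------------------------------------
# NSGA-II


def fast_non_dominated_sort(F: np.ndarray) -> np.ndarray:
    """Pareto rank (0 = non-dominated front) of each row of objective matrix F."""
    n = F.shape[0]
    ranks = np.full(n, -1, dtype=int)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for p in range(n):
        # q dominates p if q <= p everywhere and < somewhere
        le = np.all(F <= F[p], axis=1)
        lt = np.any(F < F[p], axis=1)
        dominators = np.flatnonzero(le & lt)
        n_dominating[p] = dominators.size
        ge = np.all(F >= F[p], axis=1)
        gt = np.any(F > F[p], axis=1)
        dominated_by[p] = list(np.flatnonzero(ge & gt))
    front = list(np.flatnonzero(n_dominating == 0))
    rank = 0
    while front:
        nxt: list[int] = []
        for p in front:
            ranks[p] = rank
            for q in dominated_by[p]:
                n_dominating[q] -= 1
                if n_dominating[q] == 0:
                    nxt.append(q)
        front = nxt
        rank += 1
    return ranks


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front (rows of F)."""
    n, m = F.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fmin, fmax = F[order[0], j], F[order[-1], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if fmax > fmin:
            dist[order[1:-1]] += (F[order[2:], j] - F[order[:-2], j]) / (fmax - fmin)
    return dist


def _sbx(rng, p1, p2, eta: float):
    u = rng.random(p1.size)
    beta = np.where(
        u <= 0.5, (2 * u) ** (1 / (eta + 1)), (1 / (2 * (1 - u))) ** (1 / (eta + 1))
    )
    c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return np.clip(c1, 0, 1), np.clip(c2, 0, 1)


def _poly_mutation(rng, x, eta: float, rate: float):
    y = x.copy()
    for i in range(x.size):
        if rng.random() < rate:
            u = rng.random()
            if u < 0.5:
                delta = (2 * u + (1 - 2 * u) * (1 - y[i]) ** (eta + 1)) ** (
                    1 / (eta + 1)
                ) - 1
            else:
                delta = 1 - (2 * (1 - u) + (2 * u - 1) * y[i] ** (eta + 1)) ** (
                    1 / (eta + 1)
                )
            y[i] = np.clip(y[i] + delta, 0, 1)
    return y


def nsga2(problem: Problem, config: OptimizerConfig) -> RunResult:
    """Non-dominated Sorting Genetic Algorithm II (multi-objective).

    Fast non-dominated sorting with crowding-distance truncation of the
    merged parent+child population; binary tournament on (rank, crowding);
    simulated-binary crossover (eta 15) and polynomial mutation (eta 20,
    rate 1/dimension). The final population approximates the Pareto front.
    """
    if problem.n_objectives < 2:
        raise ValueError("nsga2 requires a multi-objective problem (n_objectives >= 2)")
    started = time.time()
    rng = np.random.default_rng(config.seed)
    hp = config.hyperparams
    target = hp.get("target_error")
    eta_cx = float(hp.get("eta_crossover", 15.0))
    eta_mut = float(hp.get("eta_mutation", 20.0))
    d = problem.space.dim
    mut_rate = float(hp.get("mutation_rate", 1.0 / d))
    npop = config.pop_size

    pop = rng.random((npop, d))
    evs = problem.evaluate_unit_batch(pop)
    idxs = np.arange(npop)  # positions in the evaluation log
    F = problem.objective_matrix(evs)
    ranks = fast_non_dominated_sort(F)
    crowd = _crowding_by_front(F, ranks)

    for _ in range(config.n_generations - 1):
        if _hit_target(evs, target):
            break
        children = np.empty_like(pop)
        for i in range(0, npop, 2):
            a = _crowded_tournament(rng, ranks, crowd)
            b = _crowded_tournament(rng, ranks, crowd)
            c1, c2 = _sbx(rng, pop[a], pop[b], eta_cx)
            children[i] = _poly_mutation(rng, c1, eta_mut, mut_rate)
            if i + 1 < npop:
                children[i + 1] = _poly_mutation(rng, c2, eta_mut, mut_rate)
        child_evs = problem.evaluate_unit_batch(children)
        child_idxs = np.arange(problem.eval_counter - npop, problem.eval_counter)
        all_pop = np.vstack([pop, children])
        all_evs = list(evs) + list(child_evs)
        all_idxs = np.concatenate([idxs, child_idxs])
        allF = problem.objective_matrix(all_evs)
        all_ranks = fast_non_dominated_sort(allF)
        all_crowd = _crowding_by_front(allF, all_ranks)
        # (rank asc, crowding desc) truncation to npop
        order = np.lexsort((-all_crowd, all_ranks))[:npop]
        pop = all_pop[order]
        evs = [all_evs[i] for i in order]
        idxs = all_idxs[order]
        F = allF[order]
        ranks = fast_non_dominated_sort(F)
        crowd = _crowding_by_front(F, ranks)
    final = [
        Candidate(params=problem.eval_log[i][0], errors=ev, index=int(i))
        for i, ev in zip(idxs, evs)
    ]
    return _finish(problem, config, started, final_population=final)


def _crowding_by_front(F: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    crowd = np.zeros(F.shape[0])
    for r in np.unique(ranks):
        idx = np.flatnonzero(ranks == r)
        crowd[idx] = crowding_distance(F[idx])
    return crowd


def _crowded_tournament(rng, ranks, crowd) -> int:
    i, j = rng.integers(0, ranks.size, size=2)
    if ranks[i] < ranks[j]:
        return int(i)
    if ranks[j] < ranks[i]:
        return int(j)
    return int(i if crowd[i] >= crowd[j] else j)


# ---------------------------------------------------------------------------


def select_winner(
    population: list[Candidate], weights: Sequence[float] | None = None
) -> Candidate:
    """Pick the single preferred solution by the normalized-weighted sum of
    objectives; ties break toward the earliest-evaluated candidate."""
    if not population:
        raise ValueError("empty population")
    n_obj = len(population[0].errors.components)
    if weights is None:
        w = np.full(n_obj, 1.0 / n_obj)
    else:
        w = np.asarray(weights, dtype=float)
        if w.sum() <= 0:
            raise ValueError("weights must sum to a positive value")
        w = w / w.sum()
    best: Candidate | None = None
    best_score = np.inf
    for cand in sorted(population, key=lambda c: c.index):
        score = float(w @ cand.errors.raw)
        if score < best_score:
            best, best_score = cand, score
    assert best is not None
    return best


ALGORITHMS: dict[str, Callable[[Problem, OptimizerConfig], RunResult]] = {
    "random": random_search,
    "nelder_mead": nelder_mead,
    "ceo": ceo,
    "cmaes": cmaes,
    "pso": pso,
    "de": de,
    "nsga2": nsga2,
}

MULTI_OBJECTIVE = frozenset(["nsga2"])


def run_optimizer(problem: Problem, config: OptimizerConfig) -> RunResult:
    """Dispatch by ``config.algorithm`` name."""
    try:
        fn = ALGORITHMS[config.algorithm]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {config.algorithm!r}; known: {sorted(ALGORITHMS)}"
        ) from None
    return fn(problem, config)
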