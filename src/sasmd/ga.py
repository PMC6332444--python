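"""Multi-population genetic algorithm with information-entropy coupling.

``m`` real-coded populations evolve independently on the same box-bounded
design space.  After every generation each population j reports the best
fitness value F_j seen so far; an occurrence probability p_j (higher for
better populations, sum 1) is computed from the F_j, and each population's
search box is narrowed around its best member:

    E(K)      = (1 - p_j) E(K-1)
    lower_i(K) = max( best_i - 0.5 (1 - p_j) E_i(K), lower_i(0) )
    upper_i(K) = min( best_i + 0.5 (1 - p_j) E_i(K), upper_i(0) )

so confident (high-p) populations contract fast while the clamps guarantee
no bound ever leaves the initial design space.  The coupled problem
"minimize sum_j p_j F_j and minimize the entropy H = -sum_j p_j ln p_j"
shares its optimum with plain min_j F_j; the weighted scalarization
w1 sum p F + w2 H is tracked per generation as a convergence diagnostic.

The probability update rule and the genetic operators are deliberately
standard (the entropy/narrowing coupling is the interesting part):
softmax of per-generation standardized, negated best fitnesses (shift
invariant; a pure rank rule is available via ``p_strategy="rank"``),
tournament selection of size 2, blend crossover, Gaussian mutation scaled
to the current box, elitism of one per population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["GAConfig", "PopulationState", "EntropyState", "GAHistory",
           "init_populations", "update_probabilities", "entropy",
           "narrow_space", "aggregate_objective", "evolve"]


@dataclass(frozen=True)
class GAConfig:
    m: int = 16  # number of populations
    pop_size: int = 20  # individuals per population
    n_generations: int = 25
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15  # per-gene probability
    mutation_sigma: float = 0.1  # in units of the current per-variable extent
    entropy_weights: tuple = (1.0, 0.1)  # (w1, w2) of the scalarization
    narrowing_enabled: bool = True
    narrow_on_global_best: bool = False  # narrow around global instead of local best
    p_strategy: str = "softmax"  # "softmax" | "rank"
    softmax_temperature: float = 0.25
    early_stop_tol: float = 1e-4  # relative improvement threshold
    early_stop_patience: int = 5  # generations without improvement
    seed: int | None = None

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need at least 2 populations")
        if self.pop_size < 2:
            raise ValueError("need at least 2 individuals per population")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        w1, w2 = self.entropy_weights
        if w1 < 0 or w2 < 0 or (w1 == 0 and w2 == 0):
            raise ValueError("entropy_weights must be non-negative, not both zero")


@dataclass
class PopulationState:
    """One population: its (narrowed) box, members, and incumbent best."""

    lower: np.ndarray
    upper: np.ndarray
    initial_lower: np.ndarray
    initial_upper: np.ndarray
    space_size: np.ndarray  # E(K), the formula's bookkeeping extent
    individuals: np.ndarray  # (pop_size, n_var)
    best_member: np.ndarray | None = None
    best_fitness: float = np.inf


@dataclass(frozen=True)
class EntropyState:
    p: np.ndarray
    H: float


@dataclass
class GAHistory:
    best_f: list = field(default_factory=list)  # global best per generation
    H: list = field(default_factory=list)
    p: list = field(default_factory=list)  # (m,) per generation
    aggregate: list = field(default_factory=list)
    space_size: list = field(default_factory=list)  # (m, n_var) per generation
    n_evaluations: int = 0
    n_nonfinite: int = 0
    stopped_early: bool = False
    converged: bool = True


def _as_bounds(bounds) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(bounds, dtype=float)
    if b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("bounds must be (n_var, 2)")
    lo, hi = b[:, 0].copy(), b[:, 1].copy()
    if np.any(lo >= hi):
        raise ValueError("each variable needs lower < upper bound")
    return lo, hi


def init_populations(bounds, cfg: GAConfig, rng: np.random.Generator):
    """m populations of uniform-random members on the shared initial box."""
    lo, hi = _as_bounds(bounds)
    pops = []
    for _ in range(cfg.m):
        x = rng.uniform(lo, hi, size=(cfg.pop_size, len(lo)))
        pops.append(PopulationState(
            lower=lo.copy(), upper=hi.copy(),
            initial_lower=lo.copy(), initial_upper=hi.copy(),
            space_size=(hi - lo).copy(), individuals=x))
    return pops


def update_probabilities(best_fitnesses, strategy: str = "softmax",
                         temperature: float = 0.25) -> np.ndarray:
    """Occurrence probabilities p_j from per-population best fitnesses.

    Lower (better) fitness maps to strictly higher probability; equal
    fitnesses map to the uniform distribution; adding a constant to all
    fitnesses leaves p unchanged.
    """
    f = np.asarray(best_fitnesses, dtype=float)
    if f.ndim != 1 or len(f) < 2:
        raise ValueError("need a vector of at least 2 fitness values")
    if not np.all(np.isfinite(f)):
        raise ValueError("best fitnesses must be finite")
    if strategy == "softmax":
        sd = f.std()
        if sd == 0.0:
            return np.full(len(f), 1.0 / len(f))
        z = (f - f.mean()) / sd
        w = np.exp(-z / temperature)
    elif strategy == "rank":
        order = np.argsort(np.argsort(f, kind="stable"))  # 0 = best
        # average ranks over ties so equal fitnesses stay symmetric
        ranks = order.astype(float)
        for val in np.unique(f):
            mask = f == val
            ranks[mask] = ranks[mask].mean()
        w = len(f) - ranks
    else:
        raise ValueError(f"unknown p_j strategy {strategy!r}")
    return w / w.sum()


def entropy(p) -> float:
    """Shannon entropy H = -sum p ln p (natural log; 0 ln 0 := 0)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ValueError("probabilities must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    pz = p[p > 0]
    return float(-(pz * np.log(pz)).sum())


def narrow_space(pop: PopulationState, p_j: float, K: int,
                 rng: np.random.Generator | None = None,
                 center: np.ndarray | None = None) -> PopulationState:
    """Shrink the population's box around its best member (in place).

    Implements the narrowing recursion documented in the module docstring;
    bounds are clamped to the initial design space and members that fall
    outside the new box are re-drawn uniformly inside it.  ``center``
    overrides the contraction centre (used for global-best narrowing).
    ``K`` is the iteration index (kept for bookkeeping; the recursion state
    lives in ``pop.space_size``).
    """
    if not 0.0 <= p_j <= 1.0:
        raise ValueError("p_j must lie in [0, 1]")
    c = pop.best_member if center is None else np.asarray(center, dtype=float)
    if c is None:
        raise ValueError("population has no best member yet")
    e_new = (1.0 - p_j) * pop.space_size
    half = 0.5 * (1.0 - p_j) * e_new
    lower = np.maximum(c - half, pop.initial_lower)
    upper = np.minimum(c + half, pop.initial_upper)
    # a fully collapsed box degenerates to the (clamped) best member
    bad = lower > upper
    if np.any(bad):
        mid = np.clip(c[bad], pop.initial_lower[bad], pop.initial_upper[bad])
        lower[bad] = mid
        upper[bad] = mid
    pop.space_size = e_new
    pop.lower = lower
    pop.upper = upper
    outside = np.any((pop.individuals < lower) | (pop.individuals > upper), axis=1)
    if np.any(outside):
        if rng is None:
            rng = np.random.default_rng(0)
        pop.individuals[outside] = rng.uniform(
            lower, upper, size=(int(outside.sum()), len(lower)))
    return pop


def aggregate_objective(best_fitnesses, p, cfg: GAConfig) -> float:
    """Weighted scalarization w1 * sum_j p_j F_j + w2 * H(p)."""
    f = np.asarray(best_fitnesses, dtype=float)
    p = np.asarray(p, dtype=float)
    w1, w2 = cfg.entropy_weights
    return float(w1 * (p * f).sum() + w2 * entropy(p))


def _breed(pop: PopulationState, fitness_vals: np.ndarray,
           cfg: GAConfig, rng: np.random.Generator) -> None:
    """Selection / crossover / mutation within one population (in place)."""
    n, d = pop.individuals.shape
    x = pop.individuals
    new = np.empty_like(x)
    # elitism: the all-time best member survives unchanged
    new[0] = np.clip(pop.best_member, pop.lower, pop.upper)
    sigma = cfg.mutation_sigma * (pop.upper - pop.lower)
    for i in range(1, n):
        # tournament selection, size 2
        a, b = rng.integers(0, n, size=2)
        p1 = x[a] if fitness_vals[a] <= fitness_vals[b] else x[b]
        a, b = rng.integers(0, n, size=2)
        p2 = x[a] if fitness_vals[a] <= fitness_vals[b] else x[b]
        if rng.random() < cfg.crossover_rate:
            # blend crossover: sample around the parent interval
            u = rng.uniform(-0.5, 1.5, size=d)
            child = p1 + u * (p2 - p1)
        else:
            child = p1.copy()
        mut = rng.random(d) < cfg.mutation_rate
        if np.any(mut):
            child = child.copy()
            child[mut] += rng.normal(0.0, 1.0, size=int(mut.sum())) * sigma[mut]
        new[i] = np.clip(child, pop.lower, pop.upper)
    pop.individuals = new


def evolve(fitness: Callable, bounds, cfg: GAConfig,
           rng: np.random.Generator | None = None,
           vectorized: bool = False):
    """Minimize ``fitness`` on the box ``bounds``.

    ``fitness`` maps a variable vector to a scalar; with
    ``vectorized=True`` it maps an (N, n_var) array to an (N,) array (one
    call per generation -- this is how the direction optimizer feeds batched
    trial simulations in).  Returns ``(best_x, best_f, history)``; the
    recorded per-generation global best is non-increasing (elitism), and
    fitness values that come back non-finite are replaced by the worst
    finite value of their generation and counted in the history.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not vectorized:
        scalar_fitness = fitness

        def fitness(X):  # noqa: F811 - wrap scalar objective
            return np.array([float(scalar_fitness(x)) for x in X])

    pops = init_populations(bounds, cfg, rng)
    hist = GAHistory()
    best_x, best_f = None, np.inf
    stall = 0
    for gen in range(cfg.n_generations):
        stacked = np.vstack([pop.individuals for pop in pops])
        vals = np.asarray(fitness(stacked), dtype=float).ravel()
        if vals.shape != (len(stacked),):
            raise ValueError("fitness must return one value per individual")
        hist.n_evaluations += len(stacked)
        nonfin = ~np.isfinite(vals)
        if np.any(nonfin):
            hist.n_nonfinite += int(nonfin.sum())
            worst = vals[~nonfin].max() if np.any(~nonfin) else 0.0
            vals[nonfin] = worst
        prev_best = best_f
        per_pop_vals = vals.reshape(cfg.m, cfg.pop_size)
        for j, pop in enumerate(pops):
            i = int(np.argmin(per_pop_vals[j]))
            if per_pop_vals[j, i] < pop.best_fitness:
                pop.best_fitness = float(per_pop_vals[j, i])
                pop.best_member = pop.individuals[i].copy()
            if pop.best_fitness < best_f:
                best_f = pop.best_fitness
                best_x = pop.best_member.copy()
        best_fits = np.array([pop.best_fitness for pop in pops])
        p = update_probabilities(best_fits, cfg.p_strategy, cfg.softmax_temperature)
        hist.best_f.append(best_f)
        hist.H.append(entropy(p))
        hist.p.append(p)
        hist.aggregate.append(aggregate_objective(best_fits, p, cfg))
        hist.space_size.append(np.array([pop.space_size for pop in pops]))
        if gen == cfg.n_generations - 1:
            break
        global_best = best_x
        for j, pop in enumerate(pops):
            if cfg.narrowing_enabled:
                narrow_space(pop, float(p[j]), gen + 1, rng,
                             center=global_best if cfg.narrow_on_global_best else None)
            _breed(pop, per_pop_vals[j], cfg, rng)
        # early stopping on relative stagnation of the global best
        denom = max(abs(prev_best), 1e-12)
        if np.isfinite(prev_best) and (prev_best - best_f) / denom < cfg.early_stop_tol:
            stall += 1
        else:
            stall = 0
        if stall >= cfg.early_stop_patience:
            hist.stopped_early = True
            break
    return best_x, best_f, hist
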