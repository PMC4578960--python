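"""Improved artificial bee colony (IABC) optimizer for raster zoning.

A discrete bee-colony metaheuristic adapted to the fixed-quota cell
selection problem.  Each *food source* is a feasible assignment of
exactly Q protected cells.  One cycle runs four phases:

1. **Employed bees** — every source proposes a neighbor via the
   replace-and-alter operator against a random other source and keeps it
   greedily.
2. **Onlooker bees** — SN fitness-proportional (roulette) follows, each
   applying the same neighbor operator to the chosen source.
3. **Local search** — the cycle-best source undergoes a bounded run of
   best-improvement swap moves.
4. **Scouts** — sources stagnant for ``limit`` cycles are re-initialized.

The replace-and-alter neighbor operator copies a region from the partner
solution (R1: random rectangle; R2: the current solution's poorest
protected cells) and then toggles cells outside the region to restore
the quota (A1: best incremental-objective toggle; A2: random toggle).

All randomness flows from one ``numpy.random.Generator`` so seeded runs
are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._evaluator import IncrementalEvaluator
from .errors import ConfigurationError, InstanceError
from .model import (CompactnessSpec, Solution, SuitabilityGrid, Weights,
                    evaluate_compactness, evaluate_development,
                    evaluate_ecological, evaluate_fitness, site_score)

__all__ = [
    "IABCConfig",
    "FoodSource",
    "OptimizationResult",
    "init_complete_random",
    "init_pseudo_random",
    "initialize_population",
    "roulette_select",
    "replace_region_rect",
    "replace_region_poor",
    "alter_repair",
    "generate_neighbor",
    "swap_local_search",
    "run_iabc",
]

_EPS = 1e-12


@dataclass(frozen=True)
class IABCConfig:
    """Control parameters of one optimization run.

    Parameters
    ----------
    q : int
        Protection quota (number of cells to protect).
    weights : Weights
        Objective scalarization weights (w1, w2, w3).
    compactness : CompactnessSpec
        Neighborhood window for the density objective.
    sn : int
        Colony size: number of food sources (and of onlooker follows per
        cycle).
    limit : int
        No-improvement cycles before a source is abandoned to a scout.
    mcn : int
        Number of cycles (termination criterion).
    init_pseudo_prob : float
        Probability that a source is initialized by the score-guided
        pseudo-random method rather than uniformly.
    init_best_fraction : float
        Fraction of Q placed greedily (top site scores) in pseudo-random
        initialization; the remainder is drawn by score-proportional
        roulette.
    swap_count_range : (int, int)
        Inclusive bounds for the number of swap moves attempted per local
        search.
    p_replace_rect : float
        Probability of the rectangular replacement region (R1) over the
        poor-cells region (R2).
    p_alter_best : float
        Probability of best-improvement repair (A1) over random repair (A2).
    rng_seed : int
        Seed for the single random stream of the run.
    """

    q: int
    weights: Weights = Weights(0.34, 0.33, 0.33)
    compactness: CompactnessSpec = CompactnessSpec(3)
    sn: int = 12
    limit: int = 150
    mcn: int = 1000
    init_pseudo_prob: float = 0.5
    init_best_fraction: float = 0.5
    swap_count_range: tuple[int, int] = (20, 40)
    p_replace_rect: float = 0.5
    p_alter_best: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ConfigurationError(f"q must be >= 1, got {self.q}")
        if self.sn < 2:
            raise ConfigurationError(f"sn must be >= 2, got {self.sn}")
        if self.limit < 1:
            raise ConfigurationError(f"limit must be >= 1, got {self.limit}")
        if self.mcn < 0:
            raise ConfigurationError(f"mcn must be >= 0, got {self.mcn}")
        for name in ("init_pseudo_prob", "init_best_fraction",
                     "p_replace_rect", "p_alter_best"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.swap_count_range
        if not (0 <= lo <= hi):
            raise ConfigurationError(
                f"swap_count_range must satisfy 0 <= low <= high, got {self.swap_count_range}")


@dataclass
class FoodSource:
    """A candidate solution with its fitness and stagnation counter."""

    x: np.ndarray
    fitness: float
    trials: int = 0


@dataclass
class OptimizationResult:
    """Outcome of one IABC run."""

    best_solution: Solution
    best_fitness: float
    fitness_trace: np.ndarray          # global best per cycle, index 0 = init
    ecological_trace: np.ndarray
    development_trace: np.ndarray
    compactness_trace: np.ndarray
    scout_events: int
    degenerate_moves: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Per-cycle trace as a DataFrame (for the CSV trace file)."""
        return pd.DataFrame({
            "iteration": np.arange(len(self.fitness_trace)),
            "global_best_fitness": self.fitness_trace,
            "ecological": self.ecological_trace,
            "development": self.development_trace,
            "compactness": self.compactness_trace,
        })


# ---------------------------------------------------------------------------
# initialization


def init_complete_random(grid: SuitabilityGrid, q: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Protect q configurable cells chosen uniformly without replacement."""
    idx = np.flatnonzero(grid.configurable.ravel())
    if q > idx.size:
        raise ConfigurationError(
            f"quota {q} exceeds configurable cell count {idx.size}")
    chosen = rng.choice(idx, size=q, replace=False)
    x = np.zeros(grid.shape, dtype=bool)
    x.ravel()[chosen] = True
    return x


def _weighted_sample_without_replacement(idx: np.ndarray, weights: np.ndarray,
                                         k: int, rng: np.random.Generator) -> np.ndarray:
    """Sequential-roulette sample of k items (Efraimidis–Spirakis keys).

    Items with zero weight are drawn (uniformly) only if fewer than k items
    have positive weight.
    """
    if k == 0:
        return idx[:0]
    pos = weights > 0
    n_pos = int(pos.sum())
    if n_pos == 0:
        return rng.choice(idx, size=k, replace=False)
    keys = np.full(idx.size, -np.inf)
    u = rng.random(n_pos)
    keys[pos] = np.log(weights[pos]) - np.log(-np.log(u))
    if n_pos >= k:
        top = np.argpartition(-keys, k - 1)[:k]
        return idx[top]
    extra = rng.choice(idx[~pos], size=k - n_pos, replace=False)
    return np.concatenate([idx[pos], extra])


def _top_q_order(grid: SuitabilityGrid, scores: np.ndarray) -> np.ndarray:
    """Configurable flat indices ordered by descending score, ties by
    ascending row-major index."""
    cfg_idx = np.flatnonzero(grid.configurable.ravel())
    svals = scores.ravel()[cfg_idx]
    order = np.argsort(-svals, kind="stable")
    return cfg_idx[order]


def init_pseudo_random(grid: SuitabilityGrid, q: int, w: Weights,
                       rng: np.random.Generator,
                       best_fraction: float = 0.5) -> np.ndarray:
    """Score-guided initialization: the top ``floor(best_fraction*q)`` cells
    by site score are placed greedily; the rest are drawn by roulette with
    probability proportional to their site score (uniform fallback when all
    remaining scores are zero)."""
    cfg_count = grid.n_configurable
    if q > cfg_count:
        raise ConfigurationError(
            f"quota {q} exceeds configurable cell count {cfg_count}")
    s = site_score(grid, w)
    ordered = _top_q_order(grid, s)
    n_best = int(math.floor(best_fraction * q))
    greedy = ordered[:n_best]
    pool = ordered[n_best:]
    rest = _weighted_sample_without_replacement(
        pool, s.ravel()[pool], q - n_best, rng)
    x = np.zeros(grid.shape, dtype=bool)
    x.ravel()[greedy] = True
    x.ravel()[rest] = True
    return x


def _fitness_of(x: np.ndarray, grid: SuitabilityGrid, cfg: IABCConfig) -> float:
    return evaluate_fitness(x, grid, cfg.weights, cfg.compactness, cfg.q)


def _new_source(grid: SuitabilityGrid, cfg: IABCConfig,
                rng: np.random.Generator) -> FoodSource:
    if rng.random() < cfg.init_pseudo_prob:
        x = init_pseudo_random(grid, cfg.q, cfg.weights, rng, cfg.init_best_fraction)
    else:
        x = init_complete_random(grid, cfg.q, rng)
    return FoodSource(x, _fitness_of(x, grid, cfg), 0)


def initialize_population(grid: SuitabilityGrid, cfg: IABCConfig,
                          rng: np.random.Generator) -> list[FoodSource]:
    """Mixed initial population: each source independently uses the
    pseudo-random method with probability ``init_pseudo_prob``."""
    return [_new_source(grid, cfg, rng) for _ in range(cfg.sn)]


# ---------------------------------------------------------------------------
# neighbor generation


def roulette_select(fitnesses, rng: np.random.Generator) -> int:
    """Fitness-proportional selection; uniform fallback when all are zero."""
    f = np.asarray(fitnesses, dtype=np.float64)
    if f.size == 0:
        raise InstanceError("empty fitness list")
    if np.any(f < 0):
        raise InstanceError("roulette selection requires non-negative fitnesses")
    total = f.sum()
    if total == 0.0:
        return int(rng.integers(f.size))
    return int(np.searchsorted(np.cumsum(f), rng.random() * total, side="right"))


def replace_region_rect(u_j: np.ndarray, u_k: np.ndarray,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """R1: overwrite a random rectangle of ``u_j`` with ``u_k``'s values.

    Position is uniform over the grid; side lengths are uniform on
    [1, ceil(dim/4)]; the rectangle is clipped at the border.  Returns the
    modified array (protected count may deviate from Q) and the region as a
    boolean mask.
    """
    nr, nc = u_j.shape
    h = int(rng.integers(1, max(1, math.ceil(nr / 4)) + 1))
    wd = int(rng.integers(1, max(1, math.ceil(nc / 4)) + 1))
    r0 = int(rng.integers(nr))
    c0 = int(rng.integers(nc))
    win = (slice(r0, min(r0 + h, nr)), slice(c0, min(c0 + wd, nc)))
    out = u_j.copy()
    out[win] = u_k[win]
    region = np.zeros_like(u_j, dtype=bool)
    region[win] = True
    return out, region


def replace_region_poor(u_j: np.ndarray, u_k: np.ndarray, grid: SuitabilityGrid,
                        w: Weights, q: int,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """R2: overwrite the region formed by ``u_j``'s poorest protected cells.

    Region size is uniform on [1, ceil(0.1*q)]; quality is the site score,
    ties broken by lowest row-major index.
    """
    m_max = max(1, math.ceil(0.1 * q))
    m = int(rng.integers(1, m_max + 1))
    prot = np.flatnonzero(u_j.ravel())
    m = min(m, prot.size)
    s = site_score(grid, w).ravel()[prot]
    worst = prot[np.argsort(s, kind="stable")[:m]]
    region = np.zeros_like(u_j, dtype=bool)
    region.ravel()[worst] = True
    out = u_j.copy()
    out.ravel()[worst] = u_k.ravel()[worst]
    return out, region


def alter_repair(x: np.ndarray, region: np.ndarray, grid: SuitabilityGrid,
                 w: Weights, spec: CompactnessSpec, q: int, strategy: str,
                 rng: np.random.Generator) -> np.ndarray | None:
    """Restore the quota by toggling cells outside the replacement region.

    ``strategy`` is ``"best"`` (A1: each toggle maximizes the incremental
    objective change, ties by lowest row-major index) or ``"random"`` (A2:
    uniform among eligible cells).  Returns None when the repair is
    infeasible (no eligible cell outside the region).
    """
    if strategy not in ("best", "random"):
        raise ConfigurationError(f"unknown alter strategy {strategy!r}")
    d = int(x.sum()) - q
    if d == 0:
        return x
    outside = ~region
    removing = d > 0
    if strategy == "best":
        ev = IncrementalEvaluator(grid, w, spec, q, x)
        for _ in range(abs(d)):
            if removing:
                cand = ev.x & outside
                delta = ev.delta_remove()
            else:
                cand = ~ev.x & grid.configurable & outside
                delta = ev.delta_add()
            if not cand.any():
                return None
            flat = np.where(cand.ravel(), delta.ravel(), -np.inf)
            r, c = np.unravel_index(int(np.argmax(flat)), x.shape)
            (ev.remove if removing else ev.add)(r, c)
        return ev.x
    out = x.copy()
    for _ in range(abs(d)):
        if removing:
            cand = np.flatnonzero((out & outside).ravel())
        else:
            cand = np.flatnonzero((~out & grid.configurable & outside).ravel())
        if cand.size == 0:
            return None
        pick = int(rng.choice(cand))
        out.ravel()[pick] = not removing
    return out


def generate_neighbor(u_j: np.ndarray, u_k: np.ndarray, grid: SuitabilityGrid,
                      cfg: IABCConfig,
                      rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Replace-and-alter neighbor of ``u_j`` informed by ``u_k``.

    Returns ``(solution, degenerate)`` where ``degenerate`` is True when
    repair was infeasible and ``u_j`` was returned unchanged.
    """
    use_rect = rng.random() < cfg.p_replace_rect
    use_best = rng.random() < cfg.p_alter_best
    if use_rect:
        xm, region = replace_region_rect(u_j, u_k, rng)
    else:
        xm, region = replace_region_poor(u_j, u_k, grid, cfg.weights, cfg.q, rng)
    out = alter_repair(xm, region, grid, cfg.weights, cfg.compactness, cfg.q,
                       "best" if use_best else "random", rng)
    if out is None:
        return u_j.copy(), True
    return out, False


# ---------------------------------------------------------------------------
# local search


def swap_local_search(source: FoodSource, grid: SuitabilityGrid,
                      cfg: IABCConfig, rng: np.random.Generator) -> FoodSource:
    """Best-improvement swap descent on one source.

    Attempts up to k swaps (k uniform on ``swap_count_range``); each swap
    removes the protected cell whose removal costs least, then adds the
    unprotected configurable cell whose addition gains most, and is kept
    only if the combined change improves the objective.  Stops at the
    first non-improving swap, so fitness is non-decreasing.
    """
    lo, hi = cfg.swap_count_range
    k = int(rng.integers(lo, hi + 1))
    ev = IncrementalEvaluator(grid, cfg.weights, cfg.compactness, cfg.q, source.x)
    changed = False
    for _ in range(k):
        d_rem = np.where(ev.x.ravel(), ev.delta_remove().ravel(), -np.inf)
        a = int(np.argmax(d_rem))
        ra, ca = np.unravel_index(a, ev.x.shape)
        gain = d_rem[a]
        ev.remove(ra, ca)
        addable = ~ev.x & grid.configurable
        d_add = np.where(addable.ravel(), ev.delta_add().ravel(), -np.inf)
        b = int(np.argmax(d_add))
        rb, cb = np.unravel_index(b, ev.x.shape)
        if gain + d_add[b] > _EPS:
            ev.add(rb, cb)
            changed = True
        else:
            ev.add(ra, ca)  # revert
            break
    if not changed:
        return source
    x = ev.x.copy()
    return FoodSource(x, _fitness_of(x, grid, cfg), source.trials)


# ---------------------------------------------------------------------------
# main loop


def run_iabc(grid: SuitabilityGrid, cfg: IABCConfig,
             rng: np.random.Generator | None = None) -> OptimizationResult:
    """Run the full IABC loop for ``cfg.mcn`` cycles and return the best
    solution found, with a per-cycle global-best trace."""
    if cfg.q > grid.n_configurable:
        raise ConfigurationError(
            f"quota {cfg.q} exceeds configurable cell count {grid.n_configurable}")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)

    pop = initialize_population(grid, cfg, rng)
    best_j = int(np.argmax([fs.fitness for fs in pop]))
    gbest_x = pop[best_j].x.copy()
    gbest_f = pop[best_j].fitness

    def _sub(x):
        return (evaluate_ecological(x, grid, cfg.q),
                evaluate_development(x, grid, cfg.q),
                evaluate_compactness(x, grid, cfg.compactness, cfg.q))

    trace = [gbest_f]
    e0, v0, c0 = _sub(gbest_x)
    eco_tr, dev_tr, com_tr = [e0], [v0], [c0]
    scout_events = 0
    degenerate = 0

    def _attempt(j: int, improved: list[bool]) -> None:
        nonlocal degenerate
        k = int(rng.integers(cfg.sn - 1))
        if k >= j:
            k += 1
        xn, dg = generate_neighbor(pop[j].x, pop[k].x, grid, cfg, rng)
        degenerate += dg
        fn = _fitness_of(xn, grid, cfg)
        if fn > pop[j].fitness:
            pop[j] = FoodSource(xn, fn, pop[j].trials)
            improved[j] = True

    for _ in range(cfg.mcn):
        improved = [False] * cfg.sn
        # employed phase
        for j in range(cfg.sn):
            _attempt(j, improved)
        # onlooker phase: probabilities fixed once per cycle
        fits = [fs.fitness for fs in pop]
        for _ in range(cfg.sn):
            j = roulette_select(fits, rng)
            _attempt(j, improved)
        # local search on the cycle-best source
        jb = int(np.argmax([fs.fitness for fs in pop]))
        refined = swap_local_search(pop[jb], grid, cfg, rng)
        if refined.fitness > pop[jb].fitness:
            pop[jb] = refined
            improved[jb] = True
        # trial bookkeeping: reset on strict improvement, else one increment
        for j in range(cfg.sn):
            if improved[j]:
                pop[j].trials = 0
            else:
                pop[j].trials += 1
        # scouts
        for j in range(cfg.sn):
            if pop[j].trials >= cfg.limit:
                pop[j] = _new_source(grid, cfg, rng)
                scout_events += 1
        # store global best
        jb = int(np.argmax([fs.fitness for fs in pop]))
        if pop[jb].fitness > gbest_f:
            gbest_f = pop[jb].fitness
            gbest_x = pop[jb].x.copy()
            e0, v0, c0 = _sub(gbest_x)
        trace.append(gbest_f)
        eco_tr.append(e0)
        dev_tr.append(v0)
        com_tr.append(c0)

    return OptimizationResult(
        best_solution=Solution(gbest_x),
        best_fitness=gbest_f,
        fitness_trace=np.asarray(trace),
        ecological_trace=np.asarray(eco_tr),
        development_trace=np.asarray(dev_tr),
        compactness_trace=np.asarray(com_tr),
        scout_events=scout_events,
        degenerate_moves=degenerate,
        seed=cfg.rng_seed,
    )
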