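"""Flea optimization algorithm: population search over feature-selection masks.

Each flea is a point in [0,1]^t; thresholding at ``binarize_threshold`` turns
it into a candidate feature mask, scored by the (negated) converged LASSO
objective on the masked columns. The position update blends exploration
(resilin-weighted uniform jumps) with exploitation (a resilin-weighted convex
step toward the incumbent best plus a small Gaussian drift scaled by the
optimization learning rate). The incumbent best flea never moves (elitism),
so the best-fitness trace is monotone non-decreasing.

The published description of the update rule is not fully specified; the rule
implemented here is an artifact definition consistent with every stated
ingredient (exploration/exploitation, resilin drawn uniformly on (0,1), a
0.0001 optimization learning rate, elitist descending-fitness ranking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from fleaselect._cd import cd_gram, gram_objective
from fleaselect.dataset import FeatureDataset
from fleaselect.lasso import one_hot

#: Iteration budgets as published, keyed by magnification regime.
REGIME_ITERATIONS = {"40x": 690, "100x": 720, "200x": 700, "400x": 630}

EMPTY_MASK_FITNESS = -np.inf


@dataclass
class FOAConfig:
    population_size: int = 20
    max_iterations: int = 690
    optimization_learning_rate: float = 1e-4
    resilin_range: tuple[float, float] = (0.0, 1.0)
    alpha: float = 0.0030
    explore_probability: float = 0.1
    binarize_threshold: float = 0.5
    seed: int = 0
    fitness_max_sweeps: int = 100  # capped LASSO budget inside the loop
    fitness_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if not 0.0 <= self.explore_probability <= 1.0:
            raise ValueError("explore_probability must lie in [0, 1]")
        lo, hi = self.resilin_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("resilin_range must be an interval inside [0, 1]")


@dataclass
class FleaPopulation:
    positions: np.ndarray  # s x t, entries in [0, 1]
    fitness: np.ndarray  # length s
    best_position: np.ndarray
    best_fitness: float


@dataclass
class SelectionResult:
    mask: np.ndarray
    ranking: np.ndarray  # feature indices, descending importance
    importance: np.ndarray
    fitness_trace: np.ndarray
    n_selected: int
    candidate_mask: np.ndarray  # pre-LASSO mask (importance >= threshold)


class _MaskScorer:
    """Shared fitness kernel over precomputed Gram-space quantities.

    Features are z-scored and the one-hot targets centered once; every mask
    evaluation then works on slices of G = X^T X / n and B = X^T Y / n, so the
    sample dimension never enters the optimization loop.
    """

    def __init__(self, ds: FeatureDataset, alpha: float):
        X = ds.features
        sd = X.std(axis=0, ddof=0)
        safe = np.where(sd > 0, sd, 1.0)
        Xz = (X - X.mean(axis=0)) / safe
        Xz[:, sd == 0] = 0.0
        Y = one_hot(ds.labels)
        Y = Y - Y.mean(axis=0)
        self.alpha = alpha
        self.n = X.shape[0]
        self.t = X.shape[1]
        self.G = Xz.T @ Xz / self.n
        self.B = Xz.T @ Y / self.n
        self.yty_over_n = (Y * Y).sum(axis=0) / self.n

    def objective(self, mask: np.ndarray, tol: float, max_sweeps: int) -> float:
        """Mean converged LASSO objective over classes, on masked columns."""
        idx = np.flatnonzero(mask)
        Gm = np.ascontiguousarray(self.G[np.ix_(idx, idx)])
        Bm = np.ascontiguousarray(self.B[idx])
        psi, _, _ = cd_gram(Gm, Bm, self.alpha, tol, max_sweeps)
        per_class = gram_objective(Gm, Bm, self.yty_over_n, psi, self.alpha)
        return float(per_class.mean())

    def fitness(self, position: np.ndarray, threshold: float, tol: float, max_sweeps: int) -> float:
        mask = position >= threshold
        if not mask.any():
            return EMPTY_MASK_FITNESS
        return -self.objective(mask, tol, max_sweeps)

    def final_mask(self, candidate: np.ndarray) -> np.ndarray:
        """Full-tolerance LASSO on the candidate columns; nonzero -> selected."""
        idx = np.flatnonzero(candidate)
        Gm = np.ascontiguousarray(self.G[np.ix_(idx, idx)])
        Bm = np.ascontiguousarray(self.B[idx])
        psi, _, _ = cd_gram(Gm, Bm, self.alpha, 1e-6, 1000)
        sub = np.any(np.abs(psi) > 0, axis=1)
        mask = np.zeros(self.t, dtype=bool)
        mask[idx[sub]] = True
        return mask


def flea_fitness(
    position: np.ndarray,
    ds: FeatureDataset,
    alpha: float,
    binarize_threshold: float = 0.5,
    tol: float = 1e-4,
    max_sweeps: int = 100,
) -> float:
    """Fitness of one flea position: -J* of the masked LASSO fit.

    An empty candidate mask gets a -inf sentinel so it can never become best.
    """
    position = np.asarray(position, dtype=float)
    scorer = _MaskScorer(ds, alpha)
    return scorer.fitness(position, binarize_threshold, tol, max_sweeps)


def initialize_population(
    config: FOAConfig, t: int, rng: np.random.Generator, fitness_fn
) -> FleaPopulation:
    """i.i.d. U(0,1) positions; fitness evaluated once; best fields set."""
    if t < 1:
        raise ValueError("feature count t must be at least 1")
    positions = rng.random((config.population_size, t))
    fitness = np.array([fitness_fn(p) for p in positions])
    best = int(np.argmax(fitness))
    return FleaPopulation(
        positions=positions,
        fitness=fitness,
        best_position=positions[best].copy(),
        best_fitness=float(fitness[best]),
    )


def update_positions(
    pop: FleaPopulation, config: FOAConfig, rng: np.random.Generator, fitness_fn
) -> FleaPopulation:
    """One generation: move every non-best flea, re-evaluate, keep the elite.

    Per coordinate, with probability ``explore_probability`` the flea takes an
    exploration jump f <- r*u + (1-r)*f with u ~ U(0,1) and a fresh resilin
    draw r; otherwise it exploits: f <- f + r*(best - f) + eta*zeta with
    zeta ~ N(0,1). Positions are clipped to [0,1].
    """
    s, t = pop.positions.shape
    lo, hi = config.resilin_range
    explore = rng.random((s, t)) < config.explore_probability
    r = rng.uniform(lo, hi, (s, t))
    u = rng.random((s, t))
    zeta = rng.standard_normal((s, t))

    exploit_step = pop.positions + r * (pop.best_position[None, :] - pop.positions)
    exploit_step = exploit_step + config.optimization_learning_rate * zeta
    explore_step = r * u + (1.0 - r) * pop.positions
    new_positions = np.clip(np.where(explore, explore_step, exploit_step), 0.0, 1.0)

    best_idx = int(np.argmax(pop.fitness))
    new_positions[best_idx] = pop.positions[best_idx]  # elitism

    new_fitness = pop.fitness.copy()
    for i in range(s):
        if i != best_idx:
            new_fitness[i] = fitness_fn(new_positions[i])

    champ = int(np.argmax(new_fitness))
    best_fitness = max(pop.best_fitness, float(new_fitness[champ]))
    best_position = (
        new_positions[champ].copy()
        if new_fitness[champ] >= pop.best_fitness
        else pop.best_position
    )
    return FleaPopulation(new_positions, new_fitness, best_position, best_fitness)


def run_foa(ds: FeatureDataset, config: FOAConfig) -> SelectionResult:
    """Full selection loop: initialize, iterate, rank, final LASSO shrinkage.

    Per-feature importance is the mean position over the elite (top-fitness)
    half of the final population; the candidate mask keeps features with
    importance >= binarize_threshold, and the final mask keeps the candidates
    whose full-tolerance LASSO coefficients are nonzero.
    """
    rng = np.random.default_rng(config.seed)
    scorer = _MaskScorer(ds, config.alpha)
    fitness_fn = lambda p: scorer.fitness(
        p, config.binarize_threshold, config.fitness_tol, config.fitness_max_sweeps
    )
    pop = initialize_population(config, ds.n_features, rng, fitness_fn)
    trace = [pop.best_fitness]
    for _ in range(config.max_iterations):
        pop = update_positions(pop, config, rng, fitness_fn)
        trace.append(pop.best_fitness)

    elite_n = int(np.ceil(config.population_size / 2))
    elite_rows = np.argsort(-pop.fitness, kind="stable")[:elite_n]
    importance = pop.positions[elite_rows].mean(axis=0)
    ranking = np.argsort(-importance, kind="stable")

    candidate = importance >= config.binarize_threshold
    if not candidate.any():
        k = int(np.ceil(ds.n_features / 10))
        warnings.warn(
            f"no feature reached importance {config.binarize_threshold}; "
            f"falling back to the top {k} ranked features",
            RuntimeWarning,
            stacklevel=2,
        )
        candidate = np.zeros(ds.n_features, dtype=bool)
        candidate[ranking[:k]] = True

    mask = scorer.final_mask(candidate)
    return SelectionResult(
        mask=mask,
        ranking=ranking,
        importance=importance,
        fitness_trace=np.asarray(trace),
        n_selected=int(mask.sum()),
        candidate_mask=candidate,
    )
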