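"""Genetic-algorithm selection of a bounded gene subset for LET regression.

The model is multiple linear regression Y = b0 + b1*X1 + ... + bp*Xp fitted
by ordinary least squares, where the X are fold-change features of candidate
genes and Y is the LET value of each spaceflight sample.  Fitness of a
candidate subset is the leave-one-out cross-validated R^2, pooled over the
held-out predictions:

    R^2 = 1 - sum_q (y_q - yhat_q)^2 / sum_q (y_q - ybar)^2

where yhat_q is predicted by a model trained without sample q.  Because up to
50 features may meet as few as ~21 training samples, rank-deficient designs
are resolved by the minimum-norm least-squares solution; the honest LOOCV
score then exposes any overfitting that a training-set R^2 would hide.

The GA keeps every individual's cardinality inside [1, max_features]:
initial sizes are uniform on [1, 50]; crossover pools the union of both
parents' genes and draws the offspring size uniformly from [1, 50] (or
[1, m] when the pool has m < 50 genes); mutation removes one gene uniformly
and adds one gene the individual did not carry, preserving size exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import FCMatrix, SampleMetadata

logger = logging.getLogger(__name__)

DEFAULT_MAX_FEATURES = 50


@dataclass
class GAConfig:
    """Hyperparameters of the selector.  The seed is mandatory: every run is
    reproducible bit-for-bit from (inputs, config)."""

    rng_seed: int
    population_size: int = 100
    generations: int = 200
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    tournament_size: int = 3
    elitism: int = 1
    max_features: int = DEFAULT_MAX_FEATURES
    selection: str = "tournament"  # or "roulette"

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if self.selection not in ("tournament", "roulette"):
            raise ValueError(f"unknown selection scheme {self.selection!r}")
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Individual:
    """A candidate gene subset (feature indices into the FC matrix)."""

    genes: frozenset[int]
    fitness: float | None = None

    def __post_init__(self):
        if len(self.genes) < 1:
            raise ValueError("individual must carry at least one gene")


@dataclass
class RegressionFit:
    """OLS fit on all samples plus its LOOCV assessment."""

    intercept: float
    coefficients: np.ndarray
    loocv_predictions: np.ndarray
    r_squared: float
    pcc_actual_vs_predicted: float
    p_value: float


@dataclass
class GAResult:
    best: Individual
    selected_gene_ids: list[str]
    fit: RegressionFit
    fitness_history: pd.DataFrame  # per generation: best, mean, best_so_far
    config: GAConfig


def ols_fit(features: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares coefficients [b0, b1..bp] for target ~ 1 + features.

    Rank-deficient designs (possible whenever p >= n - 1) return the
    minimum-norm solution, so the fit is total.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    n, p = features.shape
    if n < 2 or p < 1:
        raise ValueError("need >= 2 samples and >= 1 feature")
    design = np.column_stack([np.ones(n), features])
    beta, _, rank, _ = np.linalg.lstsq(design, np.asarray(target, float),
                                       rcond=None)
    if rank < design.shape[1]:
        logger.debug("rank-deficient design (rank %d < %d); minimum-norm "
                     "solution used", rank, design.shape[1])
    return beta


def loocv_r2(features: np.ndarray, target: np.ndarray) -> RegressionFit:
    """Leave-one-out cross-validated regression assessment.

    Each sample is predicted by a model trained on the others; R^2 is the
    pooled score over all held-out predictions, and the Pearson correlation
    between actual and predicted values (with its two-sided p) is reported
    alongside.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(target, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs >= 3 samples")
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("target has zero variance; R^2 undefined")
    design = np.column_stack([np.ones(n), X])
    preds = np.empty(n)
    for q in range(n):
        mask = np.ones(n, dtype=bool)
        mask[q] = False
        beta, *_ = np.linalg.lstsq(design[mask], y[mask], rcond=None)
        preds[q] = design[q] @ beta
    r2 = 1.0 - ((y - preds) ** 2).sum() / ss_tot
    if np.std(preds) > 0:
        pcc, p = stats.pearsonr(y, preds)
    else:
        pcc, p = float("nan"), float("nan")
    beta_all = ols_fit(X, y)
    return RegressionFit(intercept=float(beta_all[0]),
                         coefficients=beta_all[1:],
                         loocv_predictions=preds,
                         r_squared=float(r2),
                         pcc_actual_vs_predicted=float(pcc),
                         p_value=float(p))


def init_population(n_features: int, config: GAConfig,
                    rng: np.random.Generator) -> list[Individual]:
    """Random individuals whose sizes are uniform on [1, min(max_features,
    n_features)] and whose members are drawn without replacement."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    hi = min(config.max_features, n_features)
    pop = []
    for _ in range(config.population_size):
        k = int(rng.integers(1, hi + 1))
        genes = frozenset(rng.choice(n_features, size=k, replace=False).tolist())
        pop.append(Individual(genes))
    return pop


def crossover(parent_a: Individual, parent_b: Individual, config: GAConfig,
              rng: np.random.Generator) -> Individual:
    """Union-pool crossover with bounded offspring size.

    The offspring draws k genes without replacement from the union of both
    parents; k is uniform on [1, max_features] when the union exceeds
    max_features, else uniform on [1, m] where m is the union size — so the
    cardinality bound can never be violated.
    """
    pool = sorted(parent_a.genes | parent_b.genes)
    m = len(pool)
    hi = config.max_features if m > config.max_features else m
    k = int(rng.integers(1, hi + 1))
    genes = frozenset(rng.choice(pool, size=k, replace=False).tolist())
    return Individual(genes)


def mutate(ind: Individual, n_features: int,
           rng: np.random.Generator) -> Individual:
    """Swap mutation: drop one gene uniformly, add one gene uniformly from
    those the individual did not carry (the dropped gene cannot return, so
    exactly one element changes and size is preserved).  If the individual
    already holds every feature there is nothing to add; it is returned
    unchanged."""
    current = sorted(ind.genes)
    outside = np.setdiff1d(np.arange(n_features), current, assume_unique=True)
    if outside.size == 0:
        logger.debug("mutation skipped: individual spans all features")
        return Individual(ind.genes, ind.fitness)
    removed = int(rng.choice(current))
    added = int(rng.choice(outside))
    return Individual(ind.genes - {removed} | {added})


def _select(pop: list[Individual], config: GAConfig,
            rng: np.random.Generator) -> Individual:
    if config.selection == "tournament":
        idx = rng.integers(0, len(pop), size=config.tournament_size)
        return max((pop[i] for i in idx), key=lambda ind: ind.fitness)
    # roulette: shift fitnesses to be positive
    fit = np.array([ind.fitness for ind in pop])
    weights = fit - fit.min() + 1e-9
    probs = weights / weights.sum()
    return pop[int(rng.choice(len(pop), p=probs))]


def run_ga(fc: FCMatrix | pd.DataFrame, metadata: SampleMetadata,
           config: GAConfig, restrict_to: list[str] | None = None,
           on_generation=None) -> GAResult:
    """Evolve a gene subset maximizing the LOOCV R^2 of the LET regression.

    Features are the FC matrix rows (optionally restricted to a gene list);
    samples are its SF columns with their LET values as the target.  Elites
    pass unchanged into the next generation; the rest is produced by
    selection, crossover with probability ``crossover_prob`` (otherwise a
    cloned parent), then mutation with probability ``mutation_prob``.
    ``on_generation(gen, population)`` is invoked after each generation's
    evaluation (gen 0 = initial population) for instrumentation.
    """
    frame = fc.frame if isinstance(fc, FCMatrix) else fc
    if restrict_to is not None:
        frame = frame.loc[[g for g in restrict_to if g in frame.index]]
    sf = frame.columns.tolist()
    if len(sf) < 5:
        raise ValueError(f"need >= 5 SF samples, got {len(sf)}")
    y = metadata.let(sf)
    X_full = frame.to_numpy(float).T  # samples x features
    gene_ids = frame.index.to_numpy()
    n_features = X_full.shape[1]

    rng = np.random.default_rng(config.rng_seed)
    cache: dict[frozenset, float] = {}

    def evaluate(ind: Individual) -> None:
        if ind.fitness is not None:
            return
        cached = cache.get(ind.genes)
        if cached is None:
            cols = sorted(ind.genes)
            cached = loocv_r2(X_full[:, cols], y).r_squared
            cache[ind.genes] = cached
        ind.fitness = cached

    pop = init_population(n_features, config, rng)
    for ind in pop:
        evaluate(ind)
    history = []

    def record(gen: int) -> None:
        fits = [ind.fitness for ind in pop]
        best = max(fits)
        prev = history[-1]["best_so_far"] if history else -np.inf
        history.append({"generation": gen, "best": best,
                        "mean": float(np.mean(fits)),
                        "best_so_far": max(best, prev)})
        if on_generation is not None:
            on_generation(gen, pop)

    record(0)
    best_ever = max(pop, key=lambda ind: ind.fitness)

    for gen in range(1, config.generations + 1):
        elites = sorted(pop, key=lambda ind: ind.fitness, reverse=True)
        new_pop = [Individual(e.genes, e.fitness) for e in elites[:config.elitism]]
        while len(new_pop) < config.population_size:
            pa = _select(pop, config, rng)
            pb = _select(pop, config, rng)
            if rng.random() < config.crossover_prob:
                child = crossover(pa, pb, config, rng)
            else:
                child = Individual((pa if rng.random() < 0.5 else pb).genes)
            if rng.random() < config.mutation_prob:
                child = mutate(child, n_features, rng)
            new_pop.append(child)
        pop = new_pop
        for ind in pop:
            evaluate(ind)
        record(gen)
        gen_best = max(pop, key=lambda ind: ind.fitness)
        if gen_best.fitness > best_ever.fitness:
            best_ever = gen_best

    cols = sorted(best_ever.genes)
    fit = loocv_r2(X_full[:, cols], y)
    return GAResult(best=best_ever,
                    selected_gene_ids=[str(g) for g in gene_ids[cols]],
                    fit=fit,
                    fitness_history=pd.DataFrame(history),
                    config=config)
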