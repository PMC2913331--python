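"""Descriptor pre-filtering and selection.

Three layers:

* ``drop_near_constant`` — the NoConstant90 pre-filter, removing
  descriptors whose modal value occurs in more than 90% of compounds;
* ``hsa_select`` — the Hybrid Selection Algorithm: a genetic algorithm
  over descriptor-subset chromosomes whose fitness is a fuzzy
  c-means class-purity index evaluated on random sub-training /
  validation partitions, followed by stepwise add/remove refinement of
  the best chromosome;
* ``greedy_wrapper_select`` — a generic greedy/best-first wrapper
  search around an arbitrary model-scoring callback.

Defaults reproduce the published processing parameters: FCM with
weighting coefficient m = 1.5, tolerance 0.001, 30 iterations and 6
clusters; GA with population 10, 8 initially active descriptors,
single-point crossover at rate 0.8, mutation 0.05, 10% rejection and
10 generations; stepwise ascending/descending coefficients +/-0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class FuzzyParams:
    weighting_coefficient: float = 1.5
    tolerance: float = 0.001
    iterations: int = 30
    clusters: int = 6


@dataclass(frozen=True)
class GeneticParams:
    population: int = 10
    initial_active: int = 8
    crossover_points: int = 1
    rejection: float = 0.1
    crossover: float = 0.8
    mutation: float = 0.05
    generations: int = 10


@dataclass(frozen=True)
class StepwiseParams:
    ascending: float = 0.02
    descending: float = -0.02


@dataclass(frozen=True)
class HSAConfig:
    fuzzy: FuzzyParams = field(default_factory=FuzzyParams)
    genetic: GeneticParams = field(default_factory=GeneticParams)
    stepwise: StepwiseParams = field(default_factory=StepwiseParams)
    seed: int = 0
    validation_fraction: float = 0.25
    fitness_repeats: int = 5

    def __post_init__(self) -> None:
        g = self.genetic
        for p in (g.rejection, g.crossover, g.mutation):
            if not 0.0 <= p <= 1.0:
                raise SelectionError("genetic probabilities must lie in [0, 1]")
        if self.fuzzy.clusters < 2:
            raise SelectionError("need at least 2 clusters")


def drop_near_constant(X: pd.DataFrame, threshold: float = 0.90) -> pd.DataFrame:
    """NoConstant90: delete columns whose modal value frequency exceeds threshold.

    Strictly "more than": a column at exactly the threshold is kept.
    """
    if X.shape[1] == 0:
        raise SelectionError("empty descriptor matrix")
    keep = []
    n = len(X)
    for col in X.columns:
        top = X[col].value_counts(dropna=False).iloc[0]
        if top / n <= threshold:
            keep.append(col)
    if not keep:
        raise SelectionError("all descriptor columns are near-constant")
    return X[keep]


def fuzzy_cmeans(
    X: np.ndarray,
    c: int,
    m: float = 1.5,
    tol: float = 0.001,
    iters: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard fuzzy c-means clustering.

    Returns (centroids of shape (c, p), membership matrix U of shape
    (n, c) with rows summing to 1).  Iteration stops when the maximum
    centroid shift falls below ``tol`` or after ``iters`` iterations.
    A degenerate start that collapses a cluster is re-seeded.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if c < 2:
        raise SelectionError("need c >= 2 clusters")
    if n < c:
        raise SelectionError(f"need at least {c} rows, got {n}")
    rng = np.random.default_rng(seed)
    for _attempt in range(5):
        U = rng.dirichlet(np.ones(c), size=n)
        centroids = _fcm_centroids(X, U, m)
        ok = True
        for _ in range(iters):
            new_U = fcm_memberships(X, centroids, m)
            new_centroids = _fcm_centroids(X, new_U, m)
            if not np.isfinite(new_centroids).all():
                ok = False
                break
            shift = float(np.abs(new_centroids - centroids).max())
            centroids, U = new_centroids, new_U
            if shift < tol:
                break
        if ok:
            return centroids, U
    raise SelectionError("fuzzy c-means failed to converge after restarts")


def _fcm_centroids(X: np.ndarray, U: np.ndarray, m: float) -> np.ndarray:
    W = U**m
    return (W.T @ X) / W.sum(axis=0)[:, None]


def fcm_memberships(X: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    """Membership matrix of points to fixed centroids (rows sum to 1)."""
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    d2 = np.where(zero, 1.0, d2)
    inv = d2 ** (-1.0 / (m - 1.0))
    U = inv / inv.sum(axis=1, keepdims=True)
    # a point sitting exactly on a centroid belongs there crisply
    rows = zero.any(axis=1)
    if rows.any():
        U[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    return U


def _purity(U: np.ndarray, y: np.ndarray, classes: Sequence) -> tuple[float, np.ndarray]:
    """Membership-weighted class purity, averaged over clusters.

    Cluster purity is the largest membership-weighted class fraction;
    the average weighs clusters by total membership.  Returns the index
    and the per-cluster majority class (for scoring held-out rows).
    """
    totals = U.sum(axis=0)
    class_mass = np.stack([U[y == cls].sum(axis=0) for cls in classes])
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = class_mass / totals[None, :]
    majority = np.argmax(class_mass, axis=0)
    purities = np.nan_to_num(fracs.max(axis=0), nan=0.0)
    weights = totals / totals.sum()
    return float((purities * weights).sum()), majority


def clustering_fitness(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    cfg: HSAConfig | None = None,
    seed: int | None = None,
) -> float:
    """Fuzzy-clustering fitness of a descriptor subset, in [0, 1].

    The rows are split at random into sub-training and validation
    parts; FCM runs on the sub-training part and the fitness is the
    mean of the membership-weighted class-purity index on both parts
    (validation rows are assigned to the fitted centroids and scored
    against the sub-training majority classes).  The index is averaged
    over ``cfg.fitness_repeats`` partitions, which keeps its sampling
    noise well below the stepwise acceptance thresholds.  Zero-variance
    subsets score 0.
    """
    cfg = cfg or HSAConfig()
    base = cfg.seed if seed is None else seed
    if cfg.fitness_repeats > 1:
        return float(
            np.mean(
                [
                    _clustering_fitness_once(X, y, cfg, base + 7919 * r)
                    for r in range(cfg.fitness_repeats)
                ]
            )
        )
    return _clustering_fitness_once(X, y, cfg, base)


def _clustering_fitness_once(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    cfg: HSAConfig,
    seed: int,
) -> float:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(list(y), dtype=object)
    if np.all(np.std(X, axis=0) <= 0):
        return 0.0
    # standardise so descriptor scale does not dominate the metric
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    rng = np.random.default_rng(seed)
    n = len(Xs)
    classes = sorted(set(y))
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    val_idx, sub_idx = order[:n_val], order[n_val:]
    c = min(cfg.fuzzy.clusters, len(sub_idx))
    if c < 2:
        return 0.0
    try:
        centroids, U_sub = fuzzy_cmeans(
            Xs[sub_idx],
            c=c,
            m=cfg.fuzzy.weighting_coefficient,
            tol=cfg.fuzzy.tolerance,
            iters=cfg.fuzzy.iterations,
            seed=int(rng.integers(2**31 - 1)),
        )
    except SelectionError:
        return 0.0
    fit_sub, majority = _purity(U_sub, y[sub_idx], classes)
    U_val = fcm_memberships(Xs[val_idx], centroids, cfg.fuzzy.weighting_coefficient)
    # held-out purity: mass agreeing with the sub-training majority class
    agree = np.stack([y[val_idx] == classes[majority[k]] for k in range(c)], axis=1)
    totals = U_val.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        val_purity = (U_val * agree).sum(axis=0) / totals
    val_purity = np.nan_to_num(val_purity, nan=0.0)
    fit_val = float((val_purity * totals / totals.sum()).sum())
    return 0.5 * (fit_sub + fit_val)


@dataclass
class Chromosome:
    mask: np.ndarray
    fitness: float = float("nan")


@dataclass
class GenerationLog:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_mask: list[int]


def hsa_select(
    X: pd.DataFrame,
    y: Sequence,
    cfg: HSAConfig | None = None,
) -> tuple[list[str], list[GenerationLog]]:
    """Hybrid Selection Algorithm: GA + stepwise with FCM fitness.

    Returns the selected descriptor names and a per-generation lineage
    log (best/mean fitness, best mask).  Bit-for-bit reproducible for
    a given (X, y, cfg.seed).
    """
    cfg = cfg or HSAConfig()
    names = list(X.columns)
    p = len(names)
    if p < 1:
        raise SelectionError("no descriptors to select from")
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(list(y), dtype=object)
    rng = np.random.default_rng(cfg.seed)
    g = cfg.genetic

    fitness_cache: dict[tuple, float] = {}

    def evaluate(mask: np.ndarray) -> float:
        if not mask.any():
            return 0.0
        key = tuple(mask.tolist())
        if key not in fitness_cache:
            # deterministic per subset: the same mask always scores the same
            mask_seed = (cfg.seed * 1_000_003 + hash(key)) % (2**31 - 1)
            fitness_cache[key] = clustering_fitness(Xv[:, mask], yv, cfg, seed=mask_seed)
        return fitness_cache[key]

    if p == 1:
        return names, []

    # -- genetic phase ------------------------------------------------------
    pop: list[Chromosome] = []
    k0 = min(g.initial_active, p)
    for _ in range(g.population):
        mask = np.zeros(p, dtype=bool)
        mask[rng.choice(p, size=k0, replace=False)] = True
        pop.append(Chromosome(mask=mask, fitness=evaluate(mask)))

    log: list[GenerationLog] = []
    for gen in range(g.generations):
        pop.sort(key=lambda ch: -ch.fitness)
        log.append(
            GenerationLog(
                generation=gen,
                best_fitness=pop[0].fitness,
                mean_fitness=float(np.mean([c.fitness for c in pop])),
                best_mask=[int(b) for b in pop[0].mask],
            )
        )
        n_reject = int(round(g.rejection * len(pop)))
        survivors = pop[: len(pop) - n_reject] if n_reject else pop
        fits = np.array([max(c.fitness, 1e-9) for c in survivors])
        probs = fits / fits.sum()
        children: list[Chromosome] = [survivors[0]]  # elitism
        while len(children) < g.population:
            i, j = rng.choice(len(survivors), size=2, p=probs)
            a, b = survivors[i].mask.copy(), survivors[j].mask.copy()
            if rng.random() < g.crossover and p > 1:
                point = int(rng.integers(1, p))
                a = np.concatenate([a[:point], b[point:]])
            flip = rng.random(p) < g.mutation
            a ^= flip
            if not a.any():
                a[int(rng.integers(p))] = True
            children.append(Chromosome(mask=a, fitness=evaluate(a)))
        pop = children

    pop.sort(key=lambda ch: -ch.fitness)
    best = pop[0]

    # -- stepwise refinement ------------------------------------------------
    mask = best.mask.copy()
    fitness = best.fitness
    seen = {tuple(mask.tolist())}
    improved = True
    while improved:
        improved = False
        # try additions
        for col in range(p):
            if mask[col]:
                continue
            trial = mask.copy()
            trial[col] = True
            key = tuple(trial.tolist())
            if key in seen:
                continue
            f = evaluate(trial)
            if f - fitness >= cfg.stepwise.ascending:
                mask, fitness, improved = trial, f, True
                seen.add(key)
                break
        if improved:
            continue
        # try removals: accept when dropping loses at most |descending|
        for col in range(p):
            if not mask[col] or mask.sum() == 1:
                continue
            trial = mask.copy()
            trial[col] = False
            key = tuple(trial.tolist())
            if key in seen:
                continue
            f = evaluate(trial)
            if f - fitness >= cfg.stepwise.descending:
                mask, fitness, improved = trial, f, True
                seen.add(key)
                break

    return [names[i] for i in range(p) if mask[i]], log


def greedy_wrapper_select(
    X: pd.DataFrame,
    y: Sequence,
    evaluator: Callable[[list[str]], float],
    direction: str = "forward",
    patience: int = 0,
) -> list[str]:
    """Greedy/best-first wrapper search over descriptor subsets.

    ``evaluator`` maps a descriptor-name list to a score (higher is
    better).  Hill-climbing with up to ``patience`` consecutive
    non-improving accepted steps (best-first backtracking): the search
    keeps the best subset ever seen and returns it.
    """
    if direction not in ("forward", "backward"):
        raise SelectionError(f"unknown direction {direction!r}")
    names = list(X.columns)
    current = [] if direction == "forward" else list(names)
    best_set = list(current)
    best_score = current_score = evaluator(current)
    stale = 0
    while True:
        candidates: list[tuple[float, list[str]]] = []
        if direction == "forward":
            for nm in names:
                if nm in current:
                    continue
                candidates.append((evaluator(current + [nm]), current + [nm]))
        else:
            for nm in current:
                trial = [x for x in current if x != nm]
                if trial:
                    candidates.append((evaluator(trial), trial))
        if not candidates:
            break
        candidates.sort(key=lambda t: (-t[0], t[1]))
        score, subset = candidates[0]
        if score > current_score:
            stale = 0
        else:
            stale += 1
            if stale > patience:
                break
        current, current_score = subset, score
        if score > best_score:
            best_score, best_set = score, list(subset)
    return best_set
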