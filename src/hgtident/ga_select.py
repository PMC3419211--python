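"""Genetic-algorithm wrapper feature-subset selection over the 15 features.

A chromosome is a 15-bit string (1 = feature selected).  Fitness is
``10000 * Recall`` with Recall as a fraction, estimated by stratified
5-fold cross-validation of the RBF-SVM restricted to the chromosome's
mask; the Mean error at that optimum is recorded alongside (it is the
tie-break and the quantity reported next to the best Recall).  The GA
uses classical fitness-proportional (roulette) selection, single-point
crossover, per-bit mutation and elitism of the top two individuals, and
runs on the imbalanced dataset (no oversampling inside the wrapper).

Defaults follow the study protocol: 100 individuals, crossover
probability 0.9, mutation probability 0.1, 200 generations, elitism 2.
Evaluations are memoized by bit pattern, so revisited subsets are free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifier import SvmConfig, fit_scaler, grid_search, predict, train
from .dataset import N_FEATURES, LabeledDataset
from .metrics import ConfusionCounts, aggregate_folds

FITNESS_SCALE = 10000.0


@dataclass(frozen=True)
class Chromosome:
    bits: tuple[int, ...]
    fitness: float = float("nan")
    recall_pct: float = float("nan")
    mean_error_pct: float = float("nan")

    @property
    def mask(self) -> np.ndarray:
        return np.array(self.bits, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(sum(self.bits))


@dataclass
class GaConfig:
    pop_size: int = 100
    crossover_p: float = 0.9
    mutation_p: float = 0.1
    generations: int = 200
    elitism: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4 or self.pop_size % 2:
            raise ValueError("pop_size must be an even integer >= 4")
        for p in (self.crossover_p, self.mutation_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


def evaluate(
    bits: tuple[int, ...] | Chromosome,
    dataset: LabeledDataset,
    svm_cfg: SvmConfig,
    cache: dict[tuple[int, ...], Chromosome] | None = None,
) -> Chromosome:
    """Fitness of one feature subset by stratified 5-fold CV.

    Per fold the scaler and the (c, g) grid search see only the training
    partition.  An all-zero mask must be repaired by the caller (run_ga
    sets one random bit) — here it is an error.
    """
    if isinstance(bits, Chromosome):
        bits = bits.bits
    bits = tuple(int(b) for b in bits)
    if len(bits) != N_FEATURES:
        raise ValueError(f"chromosome must have {N_FEATURES} bits")
    if sum(bits) == 0:
        raise ValueError("all-zero chromosome cannot be evaluated")
    if cache is not None and bits in cache:
        return cache[bits]
    mask = np.array(bits, dtype=bool)
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=svm_cfg.seed)
    folds: list[ConfusionCounts] = []
    for tr_idx, te_idx in skf.split(dataset.X, dataset.y):
        tr = dataset.subset_rows(tr_idx)
        te = dataset.subset_rows(te_idx)
        scaler = fit_scaler(tr)
        c, g = grid_search(tr, svm_cfg, mask=mask)
        model = train(tr, c, g, mask=mask, scaler=scaler)
        folds.append(ConfusionCounts.from_labels(te.y, predict(model, te)))
    res = aggregate_folds(folds)
    chrom = Chromosome(
        bits=bits,
        fitness=FITNESS_SCALE * res.recall_pct / 100.0,
        recall_pct=res.recall_pct,
        mean_error_pct=res.mean_error_pct,
    )
    if cache is not None:
        cache[bits] = chrom
    return chrom


def _sort_key(c: Chromosome) -> tuple[float, float, int]:
    """Best first: highest fitness, then lowest mean error, then fewest bits."""
    return (-c.fitness, c.mean_error_pct, c.n_selected)


def _repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if bits.sum() == 0:
        bits = bits.copy()
        bits[rng.integers(0, bits.size)] = 1
    return bits


@dataclass
class GaTrace:
    """Per-generation best-ever fitness (monotone non-decreasing) and stats."""

    best_fitness: list[float] = field(default_factory=list)
    best_recall: list[float] = field(default_factory=list)
    best_mean_error: list[float] = field(default_factory=list)
    n_evaluations: int = 0


def run_ga(
    dataset: LabeledDataset,
    ga_cfg: GaConfig,
    svm_cfg: SvmConfig,
) -> tuple[Chromosome, GaTrace]:
    """Run the GA; returns the best-ever chromosome and the fitness trace."""
    rng = np.random.default_rng(ga_cfg.seed)
    cache: dict[tuple[int, ...], Chromosome] = {}
    trace = GaTrace()

    population = [
        _repair(rng.integers(0, 2, size=N_FEATURES), rng) for _ in range(ga_cfg.pop_size)
    ]

    best_ever: Chromosome | None = None
    for _generation in range(ga_cfg.generations + 1):
        evaluated = []
        for bits in population:
            key = tuple(int(b) for b in bits)
            if key not in cache:
                trace.n_evaluations += 1
            evaluated.append(evaluate(key, dataset, svm_cfg, cache))
        evaluated.sort(key=_sort_key)
        if best_ever is None or _sort_key(evaluated[0]) < _sort_key(best_ever):
            best_ever = evaluated[0]
        trace.best_fitness.append(best_ever.fitness)
        trace.best_recall.append(best_ever.recall_pct)
        trace.best_mean_error.append(best_ever.mean_error_pct)
        if _generation == ga_cfg.generations:
            break

        # fitness-proportional (roulette) selection
        fitness = np.array([c.fitness for c in evaluated])
        weights = fitness / fitness.sum() if fitness.sum() > 0 else None
        n_children = ga_cfg.pop_size - ga_cfg.elitism
        parent_idx = rng.choice(len(evaluated), size=n_children + (n_children % 2), p=weights)
        children: list[np.ndarray] = []
        for a, b in zip(parent_idx[0::2], parent_idx[1::2]):
            pa = np.array(evaluated[a].bits)
            pb = np.array(evaluated[b].bits)
            if rng.uniform() < ga_cfg.crossover_p:
                point = int(rng.integers(1, N_FEATURES))  # single-point crossover
                ca = np.concatenate([pa[:point], pb[point:]])
                cb = np.concatenate([pb[:point], pa[point:]])
            else:
                ca, cb = pa.copy(), pb.copy()
            children.extend([ca, cb])
        children = children[:n_children]
        for child in children:
            flip = rng.uniform(size=N_FEATURES) < ga_cfg.mutation_p
            child[flip] = 1 - child[flip]
        population = [np.array(c.bits) for c in evaluated[: ga_cfg.elitism]] + [
            _repair(c, rng) for c in children
        ]

    assert best_ever is not None
    return best_ever, trace
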