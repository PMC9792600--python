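"""Weighted soft-voting ensemble with differential-evolution weights.

Each base learner's softmax output is scaled by a nonnegative weight and the
class with the highest summed probability wins.  The weights are fitted by
maximizing training accuracy with DE/rand/1/bin: uniform random
initialization inside the unit box, mutation v = a + F (b - c) with the
differential weight F dithered per generation in [F_lo, F_hi], binomial
crossover with one guaranteed mutant coordinate, and greedy selection that
keeps the parent on ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .cropping import CropSet
from .networks import BaseLearner

__all__ = ["VotingWeights", "DEConfig", "weighted_vote", "de_optimize",
           "fit_de_ensemble"]


@dataclass
class VotingWeights:
    w: np.ndarray

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.ndim != 1:
            raise ValueError("weights must be a vector")
        if np.any(self.w < 0) or np.any(self.w > 1):
            raise ValueError("weights must lie in [0, 1]")
        if not np.any(self.w > 0):
            raise ValueError("at least one weight must be positive")


@dataclass
class DEConfig:
    generations: int = 100
    population_size: int = 50
    mutation_range: tuple[float, float] = (0.5, 1.0)
    crossover_prob: float = 0.7
    bounds: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.generations < 1:
            raise ValueError("need at least one generation")
        if self.population_size < 4:
            raise ValueError("DE/rand/1 needs a population of at least 4")
        if not 0 <= self.crossover_prob <= 1:
            raise ValueError("crossover probability must be in [0, 1]")
        if self.mutation_range[0] > self.mutation_range[1]:
            raise ValueError("mutation range must be ordered")


def weighted_vote(probs: np.ndarray, weights: VotingWeights | np.ndarray
                  ) -> np.ndarray:
    """argmax_c sum_b w_b probs[b, i, c]; ties go to the lowest class index."""
    probs = np.asarray(probs)
    if probs.ndim != 3:
        raise ValueError("probs must be B x N x cls")
    w = weights.w if isinstance(weights, VotingWeights) else \
        VotingWeights(np.asarray(weights)).w
    if len(w) != probs.shape[0]:
        raise ValueError(f"{probs.shape[0]} learners but {len(w)} weights")
    summed = np.tensordot(w, probs, axes=(0, 0))
    return summed.argmax(axis=1)


def de_optimize(objective: Callable[[np.ndarray], float], n_dim: int,
                cfg: DEConfig) -> tuple[np.ndarray, list[float]]:
    """Maximize ``objective`` over the box with DE/rand/1/bin.

    Returns the best vector and the per-generation best-so-far fitness
    history (monotone non-decreasing; one entry for initialization plus one
    per generation).  Exactly population_size * (generations + 1) objective
    evaluations are performed.  Deterministic under cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bounds
    np_size = cfg.population_size
    pop = rng.uniform(lo, hi, size=(np_size, n_dim))
    # centre-of-box candidate: argmax-equivalent to uniform voting weights
    pop[0] = 0.5 * (lo + hi)
    fitness = np.array([objective(p) for p in pop])
    history = [float(fitness.max())]
    for _gen in range(cfg.generations):
        f_weight = rng.uniform(*cfg.mutation_range)   # per-generation dither
        for i in range(np_size):
            candidates = [j for j in range(np_size) if j != i]
            a, b, c = rng.choice(candidates, size=3, replace=False)
            mutant = np.clip(pop[a] + f_weight * (pop[b] - pop[c]), lo, hi)
            cross = rng.random(n_dim) < cfg.crossover_prob
            cross[rng.integers(n_dim)] = True
            trial = np.where(cross, mutant, pop[i])
            f_trial = objective(trial)
            if f_trial > fitness[i]:                  # ties keep the parent
                pop[i] = trial
                fitness[i] = f_trial
        history.append(float(fitness.max()))
    return pop[int(fitness.argmax())].copy(), history


def fit_de_ensemble(learners: list[BaseLearner], train: CropSet,
                    cfg: DEConfig) -> tuple[VotingWeights, float, list[float]]:
    """Optimize voting weights for pretrained learners on training-crop
    accuracy.  Returns (weights, achieved training accuracy, history)."""
    x = train.crops.astype(np.float32)
    y = train.labels
    probs = np.stack([ln.predict_proba(x) for ln in learners])

    def objective(w: np.ndarray) -> float:
        if not np.any(w > 0):
            return 0.0
        return float((weighted_vote(probs, VotingWeights(w)) == y).mean())

    best, history = de_optimize(objective, n_dim=len(learners), cfg=cfg)
    if not np.any(best > 0):  # degenerate corner: fall back to uniform
        best = np.full(len(learners), 0.5)
    weights = VotingWeights(best)
    return weights, objective(weights.w), history
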