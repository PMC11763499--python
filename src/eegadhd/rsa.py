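"""Reptile Search Algorithm: continuous metaheuristic + binarized feature selector.

The optimizer mimics crocodile hunting in four phases over the iteration
budget T.  With Best_k the incumbent optimum coordinate, P the percentage
difference, R the reduce function, ES the evolutionary sense and rand ~ U(0,1):

  encircling  (tau <= T/4):        x' = Best_k * (-mu) * beta - R * rand      (high walking)
              (T/4 < tau <= T/2):  x' = Best_k * x_{r1,k} * ES(tau) * rand    (belly walking)
  hunting     (T/2 < tau <= 3T/4): x' = Best_k * P * rand                     (coordination)
              (tau > 3T/4):        x' = Best_k - mu * eps - R * rand          (cooperation)

  mu  = Best_k * P
  P   = alpha + (x_{j,k} - mean(x_j)) / (Best_k * (UB_k - LB_k) + eps)
  R   = (Best_k - x_{r2,k}) / (Best_k + eps)
  ES  = 2 * r3 * (1 - tau/T),  r3 ~ U(-1, 1)

Candidates are clipped to [LB, UB] and accepted greedily (strict improvement
only), so the best-so-far trace is non-increasing by construction and the
whole run is deterministic under the config seed.

For feature selection, positions are squashed through a sigmoid and
thresholded into a mask; the wrapper fitness trades the stratified 3-fold
error of a 5-nearest-neighbour surrogate against the selected fraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RSAConfig:
    """Population, schedule, and wrapper-fitness parameters."""

    n_pop: int = 30                   # N: candidate solutions
    n_iter: int = 100                 # T: iteration budget
    n_dim: int = 1                    # problem dimensionality
    lb: float | Sequence[float] = -4.0
    ub: float | Sequence[float] = 4.0
    beta: float = 0.1                 # sensitivity of high walking
    alpha: float = 0.1               # exploration accuracy in P
    epsilon: float = 1e-10            # denominator guard
    alpha_fitness: float = 0.99       # error-vs-sparsity weight for selection
    bin_threshold: float = 0.5
    knn_k: int = 5
    cv_folds: int = 3
    cv_seed: int = 0                  # CV split seed: fixed so the fitness landscape
                                      # does not depend on the optimizer seed
    fitness_subsample: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pop < 2:
            raise ValueError("population size must be >= 2")
        if self.n_iter < 1:
            raise ValueError("iteration budget must be >= 1")
        if self.n_dim < 1:
            raise ValueError("dimensionality must be >= 1")
        if not 0 <= self.alpha_fitness <= 1:
            raise ValueError("alpha_fitness must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        lb, ub = self.bounds()
        if not np.all(lb < ub):
            raise ValueError("need LB < UB elementwise")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.broadcast_to(np.asarray(self.lb, dtype=float), (self.n_dim,)).copy()
        ub = np.broadcast_to(np.asarray(self.ub, dtype=float), (self.n_dim,)).copy()
        return lb, ub


@dataclass
class RSAState:
    """Population snapshot plus incumbent best and the seeded random stream."""

    positions: np.ndarray             # [N x n]
    fitness: np.ndarray               # [N]
    best_position: np.ndarray
    best_fitness: float
    iteration: int
    rng: np.random.Generator
    n_nonfinite: int = 0


@dataclass
class FeatureMask:
    """Binarized selection with the continuous position it came from."""

    selected: np.ndarray
    source_position: np.ndarray

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)
        if not self.selected.any():
            raise ValueError("mask must select at least one feature")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


@dataclass
class SelectionResult:
    mask: FeatureMask
    fitness: float
    trace: np.ndarray
    selected_names: list[str]
    config: RSAConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected_features": self.selected_names,
            "selected": self.mask.selected.astype(int).tolist(),
            "fitness": self.fitness,
            "trace": self.trace.tolist(),
            "config": {
                "n_pop": self.config.n_pop, "n_iter": self.config.n_iter,
                "alpha_fitness": self.config.alpha_fitness,
                "bin_threshold": self.config.bin_threshold,
                "seed": self.config.seed,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _evaluate(objective: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    value = float(objective(x))
    return value


def initialize_population(cfg: RSAConfig,
                          objective: Callable[[np.ndarray], float],
                          rng: np.random.Generator | None = None) -> RSAState:
    """Stochastic initialization x = rand * (UB - LB) + LB, then best bookkeeping."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lb, ub = cfg.bounds()
    positions = rng.uniform(size=(cfg.n_pop, cfg.n_dim)) * (ub - lb) + lb
    fitness = np.array([_evaluate(objective, x) for x in positions])
    if not np.all(np.isfinite(fitness)):
        raise ValueError("objective returned non-finite values on initial population")
    j = int(np.argmin(fitness))
    return RSAState(positions, fitness, positions[j].copy(), float(fitness[j]), 0, rng)


def evolutionary_sense(tau: int, n_iter: int, r3: float) -> float:
    """ES(tau) = 2 * r3 * (1 - tau/T): decaying, sign-alternating schedule."""
    if not 1 <= tau <= n_iter:
        raise ValueError(f"tau={tau} outside [1, T={n_iter}]")
    return 2.0 * r3 * (1.0 - tau / n_iter)


def _candidates(state: RSAState, cfg: RSAConfig, tau: int) -> np.ndarray:
    """Movement proposals for all individuals at iteration tau (vectorized)."""
    x = state.positions
    n, d = x.shape
    lb, ub = cfg.bounds()
    best = state.best_position[None, :]
    rng = state.rng
    rand = rng.uniform(size=(n, d))
    r1 = rng.integers(0, n, size=(n, d))
    r2 = rng.integers(0, n, size=(n, d))
    r3 = rng.uniform(-1.0, 1.0)
    eps = cfg.epsilon

    p = cfg.alpha + (x - x.mean(axis=1, keepdims=True)) / (best * (ub - lb)[None, :] + eps)
    mu = best * p
    r = (best - x[r2, np.arange(d)[None, :]]) / (best + eps)

    t_quarter = cfg.n_iter / 4.0
    if tau <= t_quarter:                                   # high walking
        new = best * (-mu) * cfg.beta - r * rand
    elif tau <= 2 * t_quarter:                             # belly walking
        es = evolutionary_sense(tau, cfg.n_iter, r3)
        new = best * x[r1, np.arange(d)[None, :]] * es * rand
    elif tau <= 3 * t_quarter:                             # hunting coordination
        new = best * p * rand
    else:                                                  # hunting cooperation
        new = best - mu * eps - r * rand
    return np.clip(new, lb, ub)


def update_positions(state: RSAState, cfg: RSAConfig,
                     objective: Callable[[np.ndarray], float]) -> RSAState:
    """One iteration: propose, clip, evaluate, greedily accept, track best.

    Candidates with a non-finite objective are rejected and counted in
    ``state.n_nonfinite``.  Acceptance requires strict improvement, so equal
    fitness keeps the incumbent.
    """
    tau = state.iteration + 1
    if tau > cfg.n_iter:
        raise ValueError(f"iteration {tau} exceeds budget T={cfg.n_iter}")
    new = _candidates(state, cfg, tau)
    for j in range(cfg.n_pop):
        f_new = _evaluate(objective, new[j])
        if not np.isfinite(f_new):
            state.n_nonfinite += 1
            logger.debug("rejected non-finite objective at iteration %d, individual %d",
                         tau, j)
            continue
        if f_new < state.fitness[j]:
            state.positions[j] = new[j]
            state.fitness[j] = f_new
        if state.fitness[j] < state.best_fitness:
            state.best_fitness = float(state.fitness[j])
            state.best_position = state.positions[j].copy()
    state.iteration = tau
    return state


def optimize(objective: Callable[[np.ndarray], float], cfg: RSAConfig
             ) -> tuple[np.ndarray, float, np.ndarray]:
    """Run T iterations; return best position, best fitness, best-so-far trace.

    The trace has T + 1 entries (after initialization, then after each
    iteration) and is non-increasing by the greedy acceptance contract.
    """
    state = initialize_population(cfg, objective)
    trace = [state.best_fitness]
    for _ in range(cfg.n_iter):
        update_positions(state, cfg, objective)
        trace.append(state.best_fitness)
    return state.best_position, state.best_fitness, np.array(trace)


# ---------------------------------------------------------------------------
# Binarized wrapper feature selection
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def binarize(position: np.ndarray, threshold: float = 0.5) -> FeatureMask:
    """Sigmoid transfer + threshold; an empty mask is repaired to the single
    coordinate with the largest sigmoid activation."""
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position must be finite")
    act = _sigmoid(position)
    selected = act > threshold
    if not selected.any():
        selected = np.zeros_like(selected)
        selected[int(np.argmax(act))] = True
    return FeatureMask(selected, position.copy())


def feature_selection_fitness(mask: FeatureMask | np.ndarray,
                              features: np.ndarray, labels: np.ndarray,
                              cfg: RSAConfig) -> float:
    """alpha_fitness * CV error + (1 - alpha_fitness) * selected fraction.

    CV error is the stratified k-fold (default 3) misclassification rate of a
    5-nearest-neighbour surrogate on the masked, standardized features.
    """
    selected = mask.selected if isinstance(mask, FeatureMask) else np.asarray(mask, dtype=bool)
    if not selected.any():
        raise ValueError("mask selects no features")
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    x = np.asarray(features, dtype=float)[:, selected]
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.cv_seed)
    errors = []
    for tr, te in skf.split(x, labels):
        clf = KNeighborsClassifier(n_neighbors=cfg.knn_k)
        clf.fit(x[tr], labels[tr])
        errors.append(np.mean(clf.predict(x[te]) != labels[te]))
    cv_error = float(np.mean(errors))
    frac = selected.sum() / selected.size
    return cfg.alpha_fitness * cv_error + (1 - cfg.alpha_fitness) * frac


def select_features(features: FeatureMatrix | np.ndarray, labels: np.ndarray | None,
                    cfg: RSAConfig) -> SelectionResult:
    """Wrapper selection: RSA over sigmoid-binarized masks.

    Fitness values are cached per mask (many positions binarize identically),
    and optionally computed on a seeded subsample of the instances
    (``cfg.fitness_subsample``) to keep wrapper cost bounded on large inputs.
    """
    if isinstance(features, FeatureMatrix):
        x, y = features.values, features.labels
        names = features.feature_names
    else:
        x, y = np.asarray(features, dtype=float), np.asarray(labels, dtype=int)
        names = [f"f{i}" for i in range(x.shape[1])]
    d = x.shape[1]
    if d < 1:
        raise ValueError("need at least one feature")
    cfg = replace(cfg, n_dim=d)
    if cfg.fitness_subsample is not None and cfg.fitness_subsample < len(y):
        rng = np.random.default_rng(cfg.seed + 7919)
        per_class = cfg.fitness_subsample // 2
        keep = np.concatenate([
            rng.choice(np.flatnonzero(y == c), size=min(per_class, (y == c).sum()),
                       replace=False)
            for c in (0, 1)
        ])
        x, y = x[keep], y[keep]

    cache: dict[bytes, float] = {}

    def objective(position: np.ndarray) -> float:
        m = binarize(position, cfg.bin_threshold)
        key = m.selected.tobytes()
        if key not in cache:
            cache[key] = feature_selection_fitness(m, x, y, cfg)
        return cache[key]

    best_pos, best_fit, trace = optimize(objective, cfg)
    mask = binarize(best_pos, cfg.bin_threshold)
    selected_names = [n for n, s in zip(names, mask.selected) if s]
    return SelectionResult(mask, best_fit, trace, selected_names, cfg)


def exhaustive_best_mask(features: np.ndarray, labels: np.ndarray,
                         cfg: RSAConfig) -> tuple[np.ndarray, float]:
    """Enumerate all non-empty masks (D <= ~16) and return the fitness optimum."""
    d = np.asarray(features).shape[1]
    best_mask, best_fit = None, np.inf
    for code in range(1, 2**d):
        mask = np.array([(code >> i) & 1 for i in range(d)], dtype=bool)
        fit = feature_selection_fitness(mask, features, labels, cfg)
        if fit < best_fit:
            best_mask, best_fit = mask, fit
    return best_mask, best_fit
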