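"""Binary tree-growth (BTG) metaheuristic feature selection.

The tree-growth algorithm evolves a population of continuous "tree"
positions split into four groups each iteration (after sorting by fitness):

* best group — local refinement x <- x/theta + r*x, accepted greedily;
* competition group — moves toward the two nearest best-group trees, mixed
  by the tradeoff lambda;
* removal group — the worst trees, re-initialized uniformly;
* reproduction group — recombination of random best-group trees with fresh
  random coordinates.

Positions are binarized by an S-shaped (logistic) transfer function —
bit = 1 iff sigmoid(x) > rand — to encode feature subsets (a V-shaped
transfer is available).  The subset fitness, minimized, trades classification
quality against subset size:

    fitness(mask) = alpha * (1 - CV_metric(mask)) + (1 - alpha) * |mask| / D

with the CV metric defaulting to 5-fold cross-validated accuracy of a
1-nearest-neighbor classifier (hand-vectorized over masked distances so the
thousands of fitness calls stay cheap).  The best mask ever seen is returned;
all-zero candidates are repaired by forcing one random bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from targetclp.evaluation import stratified_kfold
from targetclp.io_formats import FeatureTable

#: Continuous positions live in this box so the transfer stays responsive.
POSITION_BOUND = 4.0


def default_groups(population: int) -> tuple[int, int, int, int]:
    """Proportional 1:2:1:1 best/competition/removal/reproduction split."""
    n1 = max(1, population // 5)
    n3 = max(1, population // 5)
    n4 = max(1, population // 5)
    n2 = population - n1 - n3 - n4
    if n2 < 1:
        raise ValueError(f"population {population} too small for four groups")
    return (n1, n2, n3, n4)


@dataclass
class BTGConfig:
    """BTG hyperparameters; group sizes must sum to the population.

    ``groups=None`` uses a proportional 1:2:1:1 split (the default
    population of 30 gives 6/12/6/6).
    """

    population: int = 30
    iterations: int = 100
    groups: tuple[int, int, int, int] | None = None  # best/competition/removal/reproduction
    theta: float = 0.8
    lam: float = 0.5
    alpha: float = 0.99
    transfer: str = "s"
    seed: int = 0
    cv: int = 5

    def __post_init__(self) -> None:
        if self.groups is None:
            self.groups = default_groups(self.population)
        if sum(self.groups) != self.population:
            raise ValueError(
                f"group sizes {self.groups} must sum to population {self.population}"
            )
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.transfer not in ("s", "v"):
            raise ValueError("transfer must be 's' or 'v'")


@dataclass
class FeatureMask:
    """Binary feature-subset mask."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 1 or not self.bits.any():
            raise ValueError("feature mask must be 1-D with at least one bit set")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


class _Masked1NNEvaluator:
    """Stratified k-fold CV accuracy of 1-NN under a feature mask.

    Squared per-feature differences are precomputed once; the masked
    squared distance is then a single matrix-vector product per candidate.
    """

    def __init__(self, X, y, k: int, seed: int):
        X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(int)
        self.n, self.d = X.shape
        diff = X[:, None, :] - X[None, :, :]
        self.sq = (diff * diff).reshape(self.n * self.n, self.d).astype(np.float32)
        self.folds = stratified_kfold(self.y, k=k, seed=seed)
        self.k = k

    def accuracy(self, mask: np.ndarray) -> float:
        dist = (self.sq @ mask.astype(np.float32)).reshape(self.n, self.n)
        correct = 0
        for fold in range(self.k):
            test = np.flatnonzero(self.folds == fold)
            train = np.flatnonzero(self.folds != fold)
            nearest = train[np.argmin(dist[np.ix_(test, train)], axis=1)]
            correct += int(np.sum(self.y[nearest] == self.y[test]))
        return correct / self.n


class _EstimatorEvaluator:
    """Stratified k-fold CV accuracy of an arbitrary sklearn classifier."""

    def __init__(self, X, y, k: int, seed: int, estimator):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(int)
        self.folds = stratified_kfold(self.y, k=k, seed=seed)
        self.k = k
        self.estimator = estimator

    def accuracy(self, mask: np.ndarray) -> float:
        Xm = self.X[:, mask]
        correct = 0
        for fold in range(self.k):
            test = self.folds == fold
            est = clone(self.estimator)
            est.fit(Xm[~test], self.y[~test])
            correct += int(np.sum(est.predict(Xm[test]) == self.y[test]))
        return correct / len(self.y)


def _binarize(positions: np.ndarray, rng, transfer: str) -> np.ndarray:
    if transfer == "s":
        prob = expit(positions)
    else:  # V-shaped
        prob = np.abs(np.tanh(positions))
    return prob > rng.random(positions.shape)


def _repair(mask: np.ndarray, rng) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(len(mask))] = True
    return mask


def btg_search(fitness, d: int, cfg: BTGConfig):
    """Core BTG loop over a mask-fitness function (minimized).

    Returns (best_mask, best_fitness, trace) with the best-ever trace
    non-increasing by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    n1, n2, n3, n4 = cfg.groups
    pos = rng.uniform(-POSITION_BOUND, POSITION_BOUND, size=(cfg.population, d))
    masks = np.array([_repair(m, rng) for m in _binarize(pos, rng, cfg.transfer)])
    fit = np.array([fitness(m) for m in masks])
    best_idx = int(np.argmin(fit))
    best_mask, best_fit = masks[best_idx].copy(), float(fit[best_idx])
    trace = [best_fit]

    for _ in range(cfg.iterations):
        order = np.argsort(fit, kind="stable")
        best_g = order[:n1]
        comp_g = order[n1 : n1 + n2]
        repr_g = order[n1 + n2 : n1 + n2 + n4]
        remv_g = order[n1 + n2 + n4 :]

        # Best group: greedy local refinement.
        for j in best_g:
            r = rng.random(d)
            cand = np.clip(pos[j] / cfg.theta + r * pos[j], -POSITION_BOUND, POSITION_BOUND)
            cand_mask = _repair(_binarize(cand[None], rng, cfg.transfer)[0], rng)
            cand_fit = fitness(cand_mask)
            if cand_fit < fit[j]:
                pos[j], masks[j], fit[j] = cand, cand_mask, cand_fit

        # Competition group: move toward the two nearest best trees.
        anchors = pos[best_g]
        for j in comp_g:
            dist = np.linalg.norm(anchors - pos[j], axis=1)
            nearest = np.argsort(dist, kind="stable")[:2]
            b1 = anchors[nearest[0]]
            b2 = anchors[nearest[min(1, len(nearest) - 1)]]
            step = cfg.lam * (b1 - pos[j]) + (1 - cfg.lam) * (b2 - pos[j])
            pos[j] = np.clip(pos[j] + rng.random(d) * step, -POSITION_BOUND, POSITION_BOUND)

        # Reproduction group: recombination with a random best tree.
        for j in repr_g:
            parent = pos[rng.choice(best_g)]
            fresh = rng.uniform(-POSITION_BOUND, POSITION_BOUND, size=d)
            take = rng.random(d) < 0.5
            pos[j] = np.where(take, parent, fresh)

        # Removal group: re-initialize the worst trees.
        for j in remv_g:
            pos[j] = rng.uniform(-POSITION_BOUND, POSITION_BOUND, size=d)

        # Re-binarize and re-evaluate the moved trees.
        moved = np.concatenate([comp_g, repr_g, remv_g])
        for j in moved:
            masks[j] = _repair(_binarize(pos[j][None], rng, cfg.transfer)[0], rng)
            fit[j] = fitness(masks[j])

        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_fit:
            best_fit, best_mask = float(fit[gen_best]), masks[gen_best].copy()
        trace.append(best_fit)

    return FeatureMask(best_mask), best_fit, np.array(trace)


class BTGSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector driven by the BTG metaheuristic.

    Fitted attributes: ``support_`` / ``get_support()`` (the selected mask),
    ``best_fitness_``, ``trace_`` (best-ever fitness per iteration,
    non-increasing), ``config_`` (resolved hyperparameters).
    """

    def __init__(self, population=30, iterations=100, groups=None,
                 theta=0.8, lam=0.5, alpha=0.99, transfer="s", seed=0, cv=5,
                 inner_estimator=None):
        self.population = population
        self.iterations = iterations
        self.groups = groups
        self.theta = theta
        self.lam = lam
        self.alpha = alpha
        self.transfer = transfer
        self.seed = seed
        self.cv = cv
        self.inner_estimator = inner_estimator

    def _make_config(self) -> BTGConfig:
        return BTGConfig(
            population=self.population, iterations=self.iterations,
            groups=None if self.groups is None else tuple(self.groups),
            theta=self.theta, lam=self.lam,
            alpha=self.alpha, transfer=self.transfer, seed=self.seed, cv=self.cv,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.shape[1] < 2:
            raise ValueError("feature selection needs at least 2 features")
        cfg = self._make_config()
        if self.inner_estimator is None:
            evaluator = _Masked1NNEvaluator(X, y, cfg.cv, cfg.seed)
        else:
            evaluator = _EstimatorEvaluator(X, y, cfg.cv, cfg.seed, self.inner_estimator)
        d = X.shape[1]

        def fitness(mask):
            return cfg.alpha * (1.0 - evaluator.accuracy(mask)) + (1 - cfg.alpha) * mask.sum() / d

        mask, best_fit, trace = btg_search(fitness, d, cfg)
        self.support_ = mask.bits
        self.best_fitness_ = best_fit
        self.trace_ = trace
        self.config_ = cfg
        self.n_features_in_ = d
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def btg_select(table: FeatureTable, cfg: BTGConfig | None = None, inner_estimator=None):
    """Select features from a labelled table; returns (FeatureMask, trace)."""
    if table.labels is None:
        raise ValueError("feature table has no labels")
    cfg = cfg or BTGConfig()
    sel = BTGSelector(
        population=cfg.population, iterations=cfg.iterations, groups=cfg.groups,
        theta=cfg.theta, lam=cfg.lam, alpha=cfg.alpha, transfer=cfg.transfer,
        seed=cfg.seed, cv=cfg.cv, inner_estimator=inner_estimator,
    ).fit(table.matrix, table.labels)
    return FeatureMask(sel.support_), sel.trace_


def apply_mask(table: FeatureTable, mask: FeatureMask) -> FeatureTable:
    """Column-subset a table, preserving order and per-block bookkeeping."""
    bits = mask.bits
    if len(bits) != table.n_features:
        raise ValueError("mask length does not match table width")
    new_dims, start = [], 0
    for dim in table.block_dims:
        new_dims.append(int(bits[start : start + dim].sum()))
        start += dim
    return FeatureTable(
        table.ids, list(table.block_names), new_dims,
        table.matrix[:, bits], table.labels,
    )
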