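"""Differential-evolution learning of per-view weights and weighted fusion.

The four feature views (ESM, PSSM-CLBP, QLC, RECM-CLBP) are integrated by
scaling each block with a scalar weight w_i in [-2, 2] and concatenating.
The weight vector is learned by classic DE/rand/1/bin differential
evolution: mutation v = w_r1 + F * (w_r2 - w_r3), per-coordinate binomial
crossover with a forced coordinate k_rand, and strict greedy selection
(a trial replaces its target only when its fitness is strictly larger).
The fitness of a candidate weight vector is the mean Matthews correlation
coefficient of a classifier under stratified k-fold cross-validation on the
weighted features.

Default DE hyperparameters: population 100, 50 generations, crossover rate
0.5, scaling factor 0.5, bounds [-2, 2]; out-of-bounds mutant coordinates
are clipped.  The inner classifier defaults to a fast linear model
(logistic regression); any scikit-learn-style classifier can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from targetclp.evaluation import confusion_metrics, stratified_kfold
from targetclp.io_formats import FeatureTable

#: Fixed view order for weighting and concatenation.
VIEW_ORDER = ("ESM", "PSSM-CLBP", "QLC", "RECM-CLBP")


@dataclass
class DEConfig:
    """Differential-evolution hyperparameters."""

    n_pop: int = 100
    max_gen: int = 50
    cr: float = 0.5
    f: float = 0.5
    bounds: tuple[float, float] = (-2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pop < 4:
            raise ValueError("DE needs a population of at least 4")
        if not 0.0 <= self.cr <= 1.0:
            raise ValueError("crossover rate must be in [0, 1]")
        if self.f <= 0:
            raise ValueError("scaling factor must be positive")


@dataclass
class DEResult:
    """Outcome of one DE run."""

    w_best: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best fitness after init and after each generation
    n_evaluations: int
    seed: int
    bound_handling: str = "clip"


def weighted_concat(views, w) -> np.ndarray:
    """Scale each feature block by its scalar weight and concatenate.

    ``views`` is a FeatureTable (blocks in its own order) or a sequence of
    2-D arrays; ``w`` has one scalar per block.  Width is preserved.
    """
    if isinstance(views, FeatureTable):
        blocks = [views.block(name) for name in views.block_names]
    else:
        blocks = [np.asarray(b, dtype=float) for b in views]
    w = np.asarray(w, dtype=float).ravel()
    if len(w) != len(blocks):
        raise ValueError(f"{len(w)} weights for {len(blocks)} views")
    return np.concatenate([wi * b for wi, b in zip(w, blocks)], axis=1)


def de_optimize(fitness, cfg: DEConfig, dim: int = 4) -> DEResult:
    """Maximize ``fitness`` over [lo, hi]^dim with DE/rand/1/bin.

    Strict greedy selection: the trial replaces the target only when
    f(trial) > f(target), so ties retain the target and the best-fitness
    trace is non-decreasing.  Fully driven by the seeded generator.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bounds
    pop = rng.uniform(lo, hi, size=(cfg.n_pop, dim))

    def _eval(w: np.ndarray) -> float:
        val = float(fitness(w))
        if not np.isfinite(val):
            raise ValueError(f"non-finite fitness for candidate {w}")
        return val

    fit = np.array([_eval(w) for w in pop])
    n_evals = cfg.n_pop
    trace = [fit.max()]
    for _ in range(cfg.max_gen):
        for j in range(cfg.n_pop):
            r1, r2, r3 = rng.choice(
                [i for i in range(cfg.n_pop) if i != j], size=3, replace=False
            )
            mutant = np.clip(pop[r1] + cfg.f * (pop[r2] - pop[r3]), lo, hi)
            k_rand = rng.integers(dim)
            cross = rng.random(dim) < cfg.cr
            cross[k_rand] = True
            trial = np.where(cross, mutant, pop[j])
            trial_fit = _eval(trial)
            n_evals += 1
            if trial_fit > fit[j]:
                pop[j], fit[j] = trial, trial_fit
        trace.append(fit.max())
    best = int(np.argmax(fit))
    return DEResult(
        w_best=pop[best].copy(),
        best_fitness=float(fit[best]),
        trace=np.array(trace),
        n_evaluations=n_evals,
        seed=cfg.seed,
    )


def _mean_cv_mcc(X, y, classifier, k: int, seed: int) -> float:
    """Mean MCC of ``classifier`` over stratified k-fold CV."""
    y = np.asarray(y)
    folds = stratified_kfold(y, k=k, seed=seed)
    mccs = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {fold}: training split has a single class")
        clf = clone(classifier)
        clf.fit(X[train], y[train])
        pred = np.asarray(clf.predict(X[test]))
        tp = int(np.sum((pred == 1) & (y[test] == 1)))
        tn = int(np.sum((pred == 0) & (y[test] == 0)))
        fp = int(np.sum((pred == 1) & (y[test] == 0)))
        fn = int(np.sum((pred == 0) & (y[test] == 1)))
        mccs.append(confusion_metrics(tp, tn, fp, fn)["MCC"])
    return float(np.mean(mccs))


def cv_mcc_fitness(table: FeatureTable, w, k: int = 5, classifier=None, seed: int = 0) -> float:
    """Fitness of a weight vector: mean stratified k-fold CV MCC on the
    weighted concatenation.  Deterministic for fixed (w, seed)."""
    if table.labels is None:
        raise ValueError("feature table has no labels")
    if classifier is None:
        classifier = LogisticRegression(max_iter=1000)
    X = weighted_concat(table, w)
    return _mean_cv_mcc(X, table.labels, classifier, k, seed)


class DEWeightIntegrator(TransformerMixin, BaseEstimator):
    """Learn per-view weights by DE and apply weighted concatenation.

    Parameters
    ----------
    block_dims : per-view feature widths partitioning the input columns.
    n_pop, max_gen, cr, f, bounds, seed : DE hyperparameters (see DEConfig).
    cv : folds of the inner stratified CV used by the fitness.
    classifier : inner classifier (cloned per fold); default logistic
        regression.

    Fitted attributes: ``weights_`` (one scalar per view), ``result_``
    (full DEResult with the fitness trace).
    """

    def __init__(self, block_dims=None, n_pop=100, max_gen=50, cr=0.5, f=0.5,
                 bounds=(-2.0, 2.0), seed=0, cv=5, classifier=None):
        self.block_dims = block_dims
        self.n_pop = n_pop
        self.max_gen = max_gen
        self.cr = cr
        self.f = f
        self.bounds = bounds
        self.seed = seed
        self.cv = cv
        self.classifier = classifier

    def _blocks(self, X):
        X = np.asarray(X, dtype=float)
        dims = list(self.block_dims) if self.block_dims is not None else [X.shape[1]]
        if sum(dims) != X.shape[1]:
            raise ValueError(f"block_dims {dims} do not sum to {X.shape[1]} columns")
        out, start = [], 0
        for d in dims:
            out.append(X[:, start : start + d])
            start += d
        return out

    def fit(self, X, y):
        blocks = self._blocks(X)
        y = np.asarray(y)
        clf = self.classifier if self.classifier is not None else LogisticRegression(max_iter=1000)
        cfg = DEConfig(n_pop=self.n_pop, max_gen=self.max_gen, cr=self.cr,
                       f=self.f, bounds=tuple(self.bounds), seed=self.seed)

        def fitness(w):
            return _mean_cv_mcc(weighted_concat(blocks, w), y, clf, self.cv, self.seed)

        self.result_ = de_optimize(fitness, cfg, dim=len(blocks))
        self.weights_ = self.result_.w_best
        self.n_features_in_ = int(np.asarray(X).shape[1])
        return self

    def transform(self, X):
        check_is_fitted(self, "weights_")
        return weighted_concat(self._blocks(X), self.weights_)
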