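"""The four comparator ensembles: Merged, Unweighted, Weighting Forests,
Weighting Trees.

All four share one prediction contract,

    yhat(x) = b0 + sum_j w_j * component_j(x),

differing only in what a component is and how the weights are obtained:

* **merged** — one forest of K x m trees trained on the row-concatenation of
  all training studies; weight 1, intercept 0.
* **unweighted** — the K per-study forests, each weighted 1/K, intercept 0.
* **weighting_forests** — the K per-study forests with stacked non-negative
  ridge weights and an intercept.
* **weighting_trees** — the K x m trees extracted from those forests, each
  weighted individually by the same stacking regression.

For binary outcomes components predict class-1 probabilities and the
ensemble output is clipped to [1e-15, 1 - 1e-15] so it is always log-loss
evaluable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import joblib
import numpy as np

from .forests import ForestModel, TreePredictor, extract_trees, train_forest, train_merged
from .stacking import StackingConfig, StackingFit, build_stack_matrix, fit_stack
from .synthetic import StudyCollection

logger = logging.getLogger("treestack")

STRATEGIES = ("merged", "unweighted", "weighting_forests", "weighting_trees")
PROB_CLIP = 1e-15


@dataclass
class EnsemblePredictor:
    """A weighted combination of forests or trees with a fixed strategy label."""

    strategy: str
    components: list
    weights: np.ndarray
    intercept: float
    task: str
    n_features: int
    stacking_fit: StackingFit | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.components) != self.weights.shape[0]:
            raise ValueError("weights and components disagree in length")
        if (self.weights < 0).any():
            raise ValueError("ensemble weights must be non-negative")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected a matrix with {self.n_features} features, got shape {X.shape}"
            )
        out = np.full(X.shape[0], self.intercept, dtype=float)
        for w, comp in zip(self.weights, self.components):
            if w != 0.0:
                out += w * comp.predict(X)
        if self.task == "classification":
            out = np.clip(out, PROB_CLIP, 1.0 - PROB_CLIP)
        return out


def ensemble_predict(predictor: EnsemblePredictor, X: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`EnsemblePredictor.predict`."""
    return predictor.predict(X)


def _seed_layout(seed: int, K: int):
    """Stable seed layout shared by all strategies: K forest seeds, merged, stacking."""
    children = np.random.SeedSequence(seed).spawn(K + 2)
    ints = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    return ints[:K], ints[K], ints[K + 1]


def _train_study_forests(collection: StudyCollection, m, mtry, forest_seeds):
    return [
        train_forest(s, m=m, mtry=mtry, seed=forest_seeds[k])
        for k, s in enumerate(collection.train_studies)
    ]


@dataclass
class FittedStrategies:
    """All four ensembles fitted on one collection, sharing the same forests."""

    ensembles: dict[str, EnsemblePredictor]
    forests: list[ForestModel]
    merged: ForestModel
    forest_fit: StackingFit
    tree_fit: StackingFit

    def __getitem__(self, strategy: str) -> EnsemblePredictor:
        return self.ensembles[strategy]


def fit_ensemble(
    strategy: str,
    collection: StudyCollection,
    m: int = 10,
    mtry: int = 9,
    stacking: StackingConfig | None = None,
    seed: int = 0,
) -> EnsemblePredictor:
    """Fit one ensembling strategy on a training collection."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    K = collection.K
    forest_seeds, merged_seed, stack_seed = _seed_layout(seed, K)
    if strategy == "merged":
        merged = train_merged(collection, total_trees=K * m, mtry=mtry, seed=merged_seed)
        return EnsemblePredictor(
            strategy="merged",
            components=[merged],
            weights=np.array([1.0]),
            intercept=0.0,
            task=merged.task,
            n_features=collection.p,
        )
    if strategy != "unweighted" and K < 2:
        raise ValueError("stacked strategies need at least 2 training studies")
    forests = _train_study_forests(collection, m, mtry, forest_seeds)
    task = forests[0].task
    if strategy == "unweighted":
        return EnsemblePredictor(
            strategy="unweighted",
            components=forests,
            weights=np.full(K, 1.0 / K),
            intercept=0.0,
            task=task,
            n_features=collection.p,
        )
    cfg = stacking or StackingConfig()
    cfg = StackingConfig(**{**cfg.__dict__, "seed": stack_seed})
    if strategy == "weighting_forests":
        components = forests
    else:
        components = [t for f in forests for t in extract_trees(f)]
    stack = build_stack_matrix(components, collection, own_study=cfg.own_study)
    fit = fit_stack(stack, cfg)
    return EnsemblePredictor(
        strategy=strategy,
        components=components,
        weights=fit.weights,
        intercept=fit.intercept,
        task=task,
        n_features=collection.p,
        stacking_fit=fit,
    )


def fit_all_strategies(
    collection: StudyCollection,
    m: int = 10,
    mtry: int = 9,
    stacking: StackingConfig | None = None,
    seed: int = 0,
) -> FittedStrategies:
    """Fit all four strategies on one collection, training each forest once.

    Equivalent to four separate :func:`fit_ensemble` calls with the same
    seed, but the K per-study forests (and the merged forest) are shared.
    """
    K = collection.K
    if K < 2:
        raise ValueError("stacked strategies need at least 2 training studies")
    forest_seeds, merged_seed, stack_seed = _seed_layout(seed, K)
    forests = _train_study_forests(collection, m, mtry, forest_seeds)
    merged = train_merged(collection, total_trees=K * m, mtry=mtry, seed=merged_seed)
    task = merged.task
    cfg = stacking or StackingConfig()
    cfg = StackingConfig(**{**cfg.__dict__, "seed": stack_seed})
    trees = [t for f in forests for t in extract_trees(f)]
    stack_f = build_stack_matrix(forests, collection, own_study=cfg.own_study)
    stack_t = build_stack_matrix(trees, collection, own_study=cfg.own_study)
    fit_f = fit_stack(stack_f, cfg)
    fit_t = fit_stack(stack_t, cfg)
    p = collection.p
    ensembles = {
        "merged": EnsemblePredictor(
            "merged", [merged], np.array([1.0]), 0.0, task, p
        ),
        "unweighted": EnsemblePredictor(
            "unweighted", list(forests), np.full(K, 1.0 / K), 0.0, task, p
        ),
        "weighting_forests": EnsemblePredictor(
            "weighting_forests", list(forests), fit_f.weights, fit_f.intercept,
            task, p, stacking_fit=fit_f,
        ),
        "weighting_trees": EnsemblePredictor(
            "weighting_trees", trees, fit_t.weights, fit_t.intercept,
            task, p, stacking_fit=fit_t,
        ),
    }
    return FittedStrategies(
        ensembles=ensembles, forests=forests, merged=merged,
        forest_fit=fit_f, tree_fit=fit_t,
    )


def as_tree_level(predictor: EnsemblePredictor) -> EnsemblePredictor:
    """Re-express a forest-level ensemble tree by tree with implied weights w_k/m.

    Exact: the re-expressed predictor produces identical predictions.
    """
    if predictor.components and isinstance(predictor.components[0], TreePredictor):
        return predictor
    trees: list[TreePredictor] = []
    weights: list[float] = []
    for w, forest in zip(predictor.weights, predictor.components):
        for t in forest.trees:
            trees.append(t)
            weights.append(w / forest.m)
    return EnsemblePredictor(
        strategy=predictor.strategy,
        components=trees,
        weights=np.asarray(weights),
        intercept=predictor.intercept,
        task=predictor.task,
        n_features=predictor.n_features,
        stacking_fit=predictor.stacking_fit,
    )


def tree_level_weights(predictor: EnsemblePredictor) -> np.ndarray:
    """Per-tree weights of any strategy (implied w_k/m for forest-level ones)."""
    return as_tree_level(predictor).weights


def save_ensemble(predictor: EnsemblePredictor, path) -> None:
    joblib.dump(predictor, path)


def load_ensemble(path) -> EnsemblePredictor:
    return joblib.load(path)
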