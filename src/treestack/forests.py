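"""Per-study random forests with first-class access to their member trees.

Forests are trained with scikit-learn; each member tree is wrapped as a
:class:`TreePredictor` carrying its out-of-bag (OOB) sample indices and the
multiset of features used at its internal split nodes.  The mean of the
extracted trees' predictions reproduces the forest prediction exactly, which
is what lets a forest-level ensemble be re-expressed tree by tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .synthetic import Study, StudyCollection

logger = logging.getLogger("treestack")

DEFAULT_TREES_PER_FOREST = 10
DEFAULT_MTRY = 9


def _infer_task(outcome: np.ndarray) -> str:
    vals = np.unique(outcome)
    return "classification" if np.isin(vals, [0.0, 1.0]).all() else "regression"


@dataclass
class TreePredictor:
    """One decision tree extracted from a forest.

    ``tree_id`` is (study_id, index within forest).  For classification the
    prediction is the tree's class-1 probability, so trees and forests share
    one numeric prediction contract.
    """

    tree_id: tuple[str, int]
    estimator: object
    task: str
    oob_indices: np.ndarray
    classes_: np.ndarray | None = None

    @property
    def source_study(self) -> str:
        return self.tree_id[0]

    @property
    def split_variables(self) -> np.ndarray:
        """Feature indices used at internal nodes (one entry per split node)."""
        feats = self.estimator.tree_.feature
        return feats[feats >= 0].astype(int)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.task == "regression":
            return self.estimator.predict(X)
        proba = self.estimator.predict_proba(X)
        classes = self.estimator.classes_ if self.classes_ is None else self.classes_
        pos = np.flatnonzero(np.asarray(classes) == 1)
        if pos.size == 0:
            return np.zeros(X.shape[0])
        return proba[:, int(pos[0])]


@dataclass
class ForestModel:
    """A trained forest plus its extracted member trees.

    The forest prediction is the unweighted mean of its trees' predictions
    (class-1 probability mean for classification).
    """

    study_id: str
    model: object
    trees: list[TreePredictor]
    m: int
    mtry: int
    task: str
    n_features: int
    seed: int | None = None
    n_train: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-matrix input'}"
            )
        if self.task == "regression":
            return self.model.predict(X)
        return np.mean([t.predict(X) for t in self.trees], axis=0)

    def oob_predict(self, X: np.ndarray, fallback: bool = True) -> np.ndarray:
        """Average over only the trees for which each row is out-of-bag.

        Only meaningful when ``X`` is the forest's own training matrix.  Rows
        that are in-bag for every tree fall back to the full-forest
        prediction when ``fallback`` is set.
        """
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        num = np.zeros(n)
        cnt = np.zeros(n)
        for t in self.trees:
            mask = np.zeros(n, dtype=bool)
            oob = t.oob_indices[t.oob_indices < n]
            mask[oob] = True
            if mask.any():
                num[mask] += t.predict(X[mask])
                cnt[mask] += 1
        out = np.divide(num, cnt, out=np.zeros(n), where=cnt > 0)
        if fallback and (cnt == 0).any():
            full = self.predict(X)
            out[cnt == 0] = full[cnt == 0]
        return out


def train_forest(
    study: Study,
    m: int = DEFAULT_TREES_PER_FOREST,
    mtry: int = DEFAULT_MTRY,
    seed: int = 0,
    task: str | None = None,
    bootstrap: bool = True,
    min_samples_leaf: int | None = None,
) -> ForestModel:
    """Train one forest of ``m`` trees on a single study.

    Each tree is grown on a bootstrap sample (unless ``bootstrap`` is
    disabled, a hook used for exact-recovery checks) with ``mtry`` candidate
    features per split.  Deterministic for a given seed.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    p = study.p
    if not 1 <= mtry:
        raise ValueError("mtry must be at least 1")
    max_features = min(mtry, p)
    task = task or _infer_task(study.outcome)
    kwargs = dict(
        n_estimators=m,
        max_features=max_features,
        bootstrap=bootstrap,
        random_state=int(seed),
        n_jobs=1,
    )
    if min_samples_leaf is not None:
        kwargs["min_samples_leaf"] = min_samples_leaf
    if task == "regression":
        rf = RandomForestRegressor(**kwargs)
        y = study.outcome
    else:
        rf = RandomForestClassifier(**kwargs)
        y = study.outcome.astype(int)
    rf.fit(study.features, y)
    n = study.n
    if bootstrap:
        inbag = rf.estimators_samples_
        oobs = [np.setdiff1d(np.arange(n), np.unique(s)) for s in inbag]
    else:
        oobs = [np.array([], dtype=int) for _ in range(m)]
    classes = getattr(rf, "classes_", None)
    trees = [
        TreePredictor(
            tree_id=(study.study_id, i),
            estimator=est,
            task=task,
            oob_indices=oobs[i],
            classes_=classes,
        )
        for i, est in enumerate(rf.estimators_)
    ]
    return ForestModel(
        study_id=study.study_id,
        model=rf,
        trees=trees,
        m=m,
        mtry=max_features,
        task=task,
        n_features=p,
        seed=int(seed),
        n_train=n,
    )


def merge_studies(collection: StudyCollection) -> Study:
    """Row-concatenate all training studies into one pseudo-study."""
    train = collection.train_studies
    X = np.vstack([s.features for s in train])
    y = np.concatenate([s.outcome for s in train])
    return Study("merged", X, y, role="train")


def train_merged(
    collection: StudyCollection,
    total_trees: int | None = None,
    mtry: int = DEFAULT_MTRY,
    seed: int = 0,
    m: int = DEFAULT_TREES_PER_FOREST,
    **kwargs,
) -> ForestModel:
    """Train the Merged forest on the concatenation of all training studies.

    ``total_trees`` defaults to K x m so the Merged learner holds the same
    number of trees as the weighted ensembles it is compared against.
    """
    if total_trees is None:
        total_trees = collection.K * m
    merged = merge_studies(collection)
    return train_forest(merged, m=total_trees, mtry=mtry, seed=seed, **kwargs)


def extract_trees(forest: ForestModel) -> list[TreePredictor]:
    """The forest's member trees; their prediction mean equals the forest's."""
    return list(forest.trees)


def save_forest(forest: ForestModel, path) -> None:
    joblib.dump(forest, path)


def load_forest(path) -> ForestModel:
    return joblib.load(path)
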