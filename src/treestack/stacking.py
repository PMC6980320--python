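"""Non-negative ridge stacking of cross-study learner predictions.

The stacked design matrix ``T`` (N x J) holds, column by column, each
component learner's predictions on every training-study observation; ``Y``
stacks the true outcomes in the same row order.  The stacking weights solve

    min_{w >= 0, b0}  || Y - b0 - T w ||^2  +  lambda * ||w||^2

with an unpenalized, unconstrained intercept ``b0`` and ``lambda`` chosen by
cross-validation over a log-spaced grid.  Non-negativity rewards components
only for positive contributions; the ridge penalty shrinks rather than
zeroes, which keeps poorly cross-validating components available for new
studies instead of discarding them outright.

The solver works on the Gram matrix: with columns scaled and (when an
intercept is fitted) both sides centred, the problem reduces to a
non-negative least-squares solve on the Cholesky factor of
``T'T + lambda I``, which is exact and fast enough to sweep a 100-point
lambda grid with 10-fold cross-validation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from sklearn.model_selection import GroupKFold, KFold

from .forests import ForestModel, TreePredictor
from .synthetic import StudyCollection

logger = logging.getLogger("treestack")


@dataclass
class StackingConfig:
    """Knobs of the stacking regression (defaults match the main analyses)."""

    lambda_grid: np.ndarray | None = None
    n_lambda: int = 100
    cv_folds: int = 10
    penalty: str = "ridge"  # ridge | lasso
    intercept: bool = True
    standardize: bool = True
    own_study: str = "refit"  # refit | oob
    fold_scheme: str = "observation"  # observation | study
    seed: int = 0


@dataclass
class StackMatrix:
    """Cross-study prediction matrix T with stacked outcomes Y."""

    T: np.ndarray  # (N, J)
    Y: np.ndarray  # (N,)
    row_study: np.ndarray  # (N,) study id per row
    col_component: list  # component id per column

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.T.shape[0] != self.Y.shape[0]:
            raise ValueError("T and Y disagree on row count")
        if self.T.shape[1] != len(self.col_component):
            raise ValueError("column ids do not match T's width")
        if np.isnan(self.T).any() or np.isnan(self.Y).any():
            raise ValueError("stack matrix contains missing values")

    @property
    def N(self) -> int:
        return self.T.shape[0]

    @property
    def J(self) -> int:
        return self.T.shape[1]


@dataclass
class StackingFit:
    """Fitted stacking weights with the cross-validation audit trail."""

    weights: np.ndarray
    intercept: float
    lambda_: float
    penalty: str
    cv_folds: int
    lambda_grid: np.ndarray
    cv_curve: np.ndarray  # mean CV squared error per grid point
    col_component: list = field(default_factory=list)

    def predict_from_stack(self, T: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(T, dtype=float) @ self.weights


def _component_id(component) -> object:
    if isinstance(component, ForestModel):
        return component.study_id
    if isinstance(component, TreePredictor):
        return component.tree_id
    return getattr(component, "component_id", repr(component))


def _component_source(component) -> str | None:
    if isinstance(component, ForestModel):
        return component.study_id
    if isinstance(component, TreePredictor):
        return component.source_study
    return None


def build_stack_matrix(
    components: list,
    collection: StudyCollection,
    own_study: str = "refit",
) -> StackMatrix:
    """Stack every component's predictions on every training observation.

    Component j's predictions on its own source study are, by default, the
    ordinary refit predictions.  With ``own_study='oob'`` a forest
    component's own-study rows are replaced by its out-of-bag prediction
    (rows never out-of-bag fall back to the refit value); a single tree's
    prediction does not change with bag membership, so the flag leaves tree
    components untouched.
    """
    if own_study not in ("refit", "oob"):
        raise ValueError(f"unknown own_study mode {own_study!r}")
    train = collection.train_studies
    Y = np.concatenate([s.outcome for s in train])
    row_study = np.concatenate([np.repeat(s.study_id, s.n) for s in train])
    cols = []
    for comp in components:
        source = _component_source(comp)
        parts = []
        for s in train:
            if (
                own_study == "oob"
                and source == s.study_id
                and isinstance(comp, ForestModel)
            ):
                parts.append(comp.oob_predict(s.features))
            else:
                parts.append(comp.predict(s.features))
        cols.append(np.concatenate(parts))
    T = np.column_stack(cols) if cols else np.empty((Y.shape[0], 0))
    return StackMatrix(
        T=T, Y=Y, row_study=row_study, col_component=[_component_id(c) for c in components]
    )


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


def _nnls_gram(Q: np.ndarray, b: np.ndarray) -> np.ndarray:
    """argmin_{w>=0} (1/2) w'Qw - b'w for symmetric positive-definite Q."""
    L = np.linalg.cholesky(Q)
    z = scipy.linalg.solve_triangular(L, b, lower=True)
    w, _ = scipy.optimize.nnls(L.T, z)
    return w


def _solve_path_point(
    G: np.ndarray, b: np.ndarray, lam: float, penalty: str
) -> np.ndarray:
    J = G.shape[0]
    if penalty == "ridge":
        return _nnls_gram(G + lam * np.eye(J), b)
    # non-negative lasso: the L1 term is linear on the feasible set
    jitter = 1e-10 * max(np.trace(G) / max(J, 1), 1.0)
    return _nnls_gram(G + jitter * np.eye(J), b - lam)


def _fit_at_lambda(
    T: np.ndarray, y: np.ndarray, lam: float, penalty: str, intercept: bool
) -> tuple[np.ndarray, float]:
    if intercept:
        mu_T, mu_y = T.mean(axis=0), y.mean()
    else:
        mu_T, mu_y = np.zeros(T.shape[1]), 0.0
    Tc, yc = T - mu_T, y - mu_y
    G = Tc.T @ Tc
    b = Tc.T @ yc
    w = _solve_path_point(G, b, lam, penalty)
    b0 = float(mu_y - mu_T @ w)
    return w, b0


def default_lambda_grid(
    T: np.ndarray, y: np.ndarray, n_lambda: int = 100, intercept: bool = True
) -> np.ndarray:
    """Log-spaced descending grid scaled to the data (glmnet-style anchor)."""
    Tc = T - T.mean(axis=0) if intercept else T
    yc = y - y.mean() if intercept else y
    ref = float(np.max(np.abs(Tc.T @ yc))) if T.size else 1.0
    if not np.isfinite(ref) or ref <= 0:
        ref = 1.0
    return ref * np.logspace(1, -5, n_lambda)


def solve_nn_ridge(
    stack: StackMatrix,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 10,
    penalty: str = "ridge",
    seed: int = 0,
    intercept: bool = True,
    standardize: bool = True,
    fold_scheme: str = "observation",
    n_lambda: int = 100,
) -> StackingFit:
    """Fit non-negative, ridge-penalized stacking weights with CV-chosen lambda.

    Columns are internally scaled to unit standard deviation before
    penalization and the weights back-transformed (non-negativity survives
    positive scaling); all-constant columns get weight 0 with a warning.
    """
    if penalty not in ("ridge", "lasso"):
        raise ValueError(f"unknown penalty {penalty!r}")
    T_raw, y = stack.T, stack.Y
    N, J = T_raw.shape
    if cv_folds < 2:
        raise ValueError("cv_folds must be at least 2")
    if N <= cv_folds:
        raise ValueError("need more observations than CV folds")

    sd = T_raw.std(axis=0)
    keep = sd > 0
    if standardize:
        if not keep.all():
            warnings.warn(
                f"{int((~keep).sum())} constant stack column(s) received weight 0",
                RuntimeWarning,
                stacklevel=2,
            )
        scale = np.where(keep, sd, 1.0)
        T = T_raw[:, keep] / scale[keep]
    else:
        T = T_raw[:, keep] if not keep.all() else T_raw
        if not keep.all():
            warnings.warn(
                f"{int((~keep).sum())} constant stack column(s) received weight 0",
                RuntimeWarning,
                stacklevel=2,
            )
        scale = np.ones(J)

    if lambda_grid is None:
        lambda_grid = default_lambda_grid(T, y, n_lambda=n_lambda, intercept=intercept)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda_grid must be non-empty")

    if fold_scheme == "observation":
        splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=int(seed))
        splits = list(splitter.split(T))
    elif fold_scheme == "study":
        groups = stack.row_study
        n_groups = len(np.unique(groups))
        splitter = GroupKFold(n_splits=min(cv_folds, n_groups))
        splits = list(splitter.split(T, groups=groups))
    else:
        raise ValueError(f"unknown fold_scheme {fold_scheme!r}")

    cv_err = np.zeros(lambda_grid.size)
    for tr, va in splits:
        Ttr, ytr = T[tr], y[tr]
        if intercept:
            mu_T, mu_y = Ttr.mean(axis=0), ytr.mean()
        else:
            mu_T, mu_y = np.zeros(T.shape[1]), 0.0
        Tc, yc = Ttr - mu_T, ytr - mu_y
        G = Tc.T @ Tc
        b = Tc.T @ yc
        for i, lam in enumerate(lambda_grid):
            w = _solve_path_point(G, b, lam, penalty)
            b0 = mu_y - mu_T @ w
            resid = y[va] - b0 - T[va] @ w
            cv_err[i] += float(resid @ resid)
    cv_err /= N
    best = int(np.argmin(cv_err))
    lam = float(lambda_grid[best])

    w_kept, b0 = _fit_at_lambda(T, y, lam, penalty, intercept)
    weights = np.zeros(J)
    if standardize:
        weights[keep] = w_kept / scale[keep]
    else:
        weights[keep] = w_kept
    logger.debug(
        "stacking fit: J=%d N=%d penalty=%s lambda=%.4g nonzero=%d",
        J, N, penalty, lam, int((weights > 0).sum()),
    )
    return StackingFit(
        weights=weights,
        intercept=b0,
        lambda_=lam,
        penalty=penalty,
        cv_folds=cv_folds,
        lambda_grid=lambda_grid,
        cv_curve=cv_err,
        col_component=list(stack.col_component),
    )


def fit_stack(stack: StackMatrix, config: StackingConfig | None = None) -> StackingFit:
    """Convenience wrapper: fit a :class:`StackMatrix` under a config."""
    cfg = config or StackingConfig()
    return solve_nn_ridge(
        stack,
        lambda_grid=cfg.lambda_grid,
        cv_folds=cfg.cv_folds,
        penalty=cfg.penalty,
        seed=cfg.seed,
        intercept=cfg.intercept,
        standardize=cfg.standardize,
        fold_scheme=cfg.fold_scheme,
        n_lambda=cfg.n_lambda,
    )


def implied_tree_weights(fit: StackingFit, m: int) -> np.ndarray:
    """Tree-level weights implied by a forest-level fit: each tree gets w_k / m."""
    if m < 1:
        raise ValueError("m must be at least 1")
    return np.repeat(fit.weights, m) / m


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_stack_matrix(stack: StackMatrix, path) -> None:
    """Delimited-text export: one column per component plus study id and Y."""
    df = pd.DataFrame(stack.T, columns=[str(c) for c in stack.col_component])
    df["study_id"] = stack.row_study
    df["Y"] = stack.Y
    df.to_csv(path, index=False)


def read_stack_matrix(path) -> StackMatrix:
    df = pd.read_csv(path)
    meta = df[["study_id", "Y"]]
    T = df.drop(columns=["study_id", "Y"])
    return StackMatrix(
        T=T.to_numpy(dtype=float),
        Y=meta["Y"].to_numpy(dtype=float),
        row_study=meta["study_id"].to_numpy(),
        col_component=list(T.columns),
    )


def save_fit(fit: StackingFit, path) -> None:
    payload = {
        "weights": fit.weights.tolist(),
        "intercept": fit.intercept,
        "lambda": fit.lambda_,
        "penalty": fit.penalty,
        "cv_folds": fit.cv_folds,
        "lambda_grid": np.asarray(fit.lambda_grid).tolist(),
        "cv_curve": np.asarray(fit.cv_curve).tolist(),
        "col_component": [list(c) if isinstance(c, tuple) else c for c in fit.col_component],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_fit(path) -> StackingFit:
    with open(path) as fh:
        payload = json.load(fh)
    return StackingFit(
        weights=np.asarray(payload["weights"], dtype=float),
        intercept=float(payload["intercept"]),
        lambda_=float(payload["lambda"]),
        penalty=payload["penalty"],
        cv_folds=int(payload["cv_folds"]),
        lambda_grid=np.asarray(payload["lambda_grid"], dtype=float),
        cv_curve=np.asarray(payload["cv_curve"], dtype=float),
        col_component=[tuple(c) if isinstance(c, list) else c for c in payload["col_component"]],
    )
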