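"""Tree-structure summaries, permutation variable importance and
weight-distribution diagnostics.

These are the instruments for asking *why* a tree earns a large or small
stacking weight: how often its splits use outcome-associated ("true")
features, how many interaction-involved features it touches, and how the
out-of-bag permutation importance mass distributes over true features —
summarized within weight-decile bands (bottom 10%, top 10%, overall).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensembles import EnsemblePredictor, as_tree_level
from .forests import TreePredictor
from .stacking import StackingFit, implied_tree_weights
from .synthetic import GenerativeModel, Study

logger = logging.getLogger("treestack")


@dataclass
class TreeStructureSummary:
    """Per-tree structural metrics relative to the generative model."""

    tree_id: tuple
    weight: float
    freq_true_vars: float  # fraction of split nodes using a true feature
    n_interaction_vars: int  # distinct interaction features among split vars
    prop_true_varimp: float = float("nan")


@dataclass
class WeightDecileSummary:
    """Mean tree-level weight in the bottom-decile, top-decile and overall bands."""

    n: int
    band_size: int
    overall_mean: float
    bottom_mean: float | None
    top_mean: float | None
    bottom_bound: float | None  # largest weight inside the bottom band
    top_bound: float | None  # smallest weight inside the top band


def tree_structure_metrics(
    tree: TreePredictor, model: GenerativeModel, weight: float = float("nan")
) -> TreeStructureSummary:
    """Frequency of true features and count of interaction features in one tree.

    ``freq_true_vars`` is the fraction of internal split nodes whose split
    feature is outcome-associated; a tree with no splits reports 0.
    ``n_interaction_vars`` counts how many distinct interaction-involved
    features appear among the tree's split features (0..3).
    """
    splits = tree.split_variables
    if splits.size == 0:
        freq = 0.0
    else:
        freq = float(np.isin(splits, model.true_idx).mean())
    n_inter = int(np.isin(model.interaction_idx, np.unique(splits)).sum())
    return TreeStructureSummary(
        tree_id=tree.tree_id,
        weight=float(weight),
        freq_true_vars=freq,
        n_interaction_vars=n_inter,
    )


def _oob_mse_differences(
    trees: list[TreePredictor],
    studies: dict[str, Study],
    rng: np.random.Generator,
    p: int,
) -> tuple[np.ndarray, list[int]]:
    """Per-tree, per-feature OOB MSE increase under permutation.

    Returns a (n_used_trees, p) matrix of differences (permuted MSE minus
    baseline MSE) and the indices of trees that were skipped for having an
    empty out-of-bag set.  Features a tree never splits on contribute an
    exact 0 (permuting them cannot change that tree's predictions).
    """
    rows = []
    skipped = []
    for i, tree in enumerate(trees):
        study = studies[tree.source_study]
        oob = tree.oob_indices
        if oob.size == 0:
            skipped.append(i)
            continue
        Xo = study.features[oob]
        yo = study.outcome[oob]
        base = float(np.mean((tree.predict(Xo) - yo) ** 2))
        diffs = np.zeros(p)
        for j in np.unique(tree.split_variables):
            Xp = Xo.copy()
            Xp[:, j] = Xo[rng.permutation(Xo.shape[0]), j]
            diffs[j] = float(np.mean((tree.predict(Xp) - yo) ** 2)) - base
        rows.append(diffs)
    if skipped:
        warnings.warn(
            f"{len(skipped)} tree(s) without out-of-bag samples skipped in "
            "permutation importance",
            RuntimeWarning,
            stacklevel=2,
        )
    return (np.vstack(rows) if rows else np.empty((0, p))), skipped


def _normalize_importance(diffs: np.ndarray) -> np.ndarray:
    """Mean over trees of the MSE differences, scaled by their standard deviation.

    Features with zero spread across trees (in particular features no tree
    uses, whose differences are identically 0) keep their raw mean.
    """
    if diffs.shape[0] < 2:
        raise ValueError("permutation importance needs at least 2 usable trees")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    out = mean.copy()
    nz = sd > 0
    out[nz] = mean[nz] / sd[nz]
    return out


def permutation_importance(
    trees: list[TreePredictor],
    studies: dict[str, Study],
    seed: int = 0,
) -> np.ndarray:
    """Out-of-bag permutation importance over a set of trees.

    For each tree, the OOB mean squared error is recorded before and after
    permuting each feature column; the per-feature differences are averaged
    over trees and normalized by their standard deviation.  Deterministic
    for a given seed.
    """
    if not trees:
        raise ValueError("no trees supplied")
    p = studies[trees[0].source_study].p
    rng = np.random.default_rng(seed)
    diffs, _ = _oob_mse_differences(trees, studies, rng, p)
    return _normalize_importance(diffs)


def proportion_true_varimp(importance: np.ndarray, true_idx: np.ndarray) -> float:
    """Share of total variable-importance mass carried by the true features.

    Negative importances are floored at 0 first so the share lies in [0, 1].
    """
    imp = np.clip(np.asarray(importance, dtype=float), 0.0, None)
    total = imp.sum()
    if total == 0:
        warnings.warn("all importances are zero; returning 0", RuntimeWarning, stacklevel=2)
        return 0.0
    return float(imp[np.asarray(true_idx, dtype=int)].sum() / total)


def weight_decile_summary(weights: np.ndarray) -> WeightDecileSummary:
    """Band means of a tree-weight vector: bottom 10%, top 10%, overall.

    Bands are formed on order statistics (stable sort, ties broken by
    component index).  With fewer than 10 weights only the overall band is
    reported.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    overall = float(w.mean())
    k = n // 10
    if k < 1:
        return WeightDecileSummary(
            n=n, band_size=0, overall_mean=overall,
            bottom_mean=None, top_mean=None, bottom_bound=None, top_bound=None,
        )
    order = np.argsort(w, kind="stable")
    bottom = w[order[:k]]
    top = w[order[n - k:]]
    return WeightDecileSummary(
        n=n,
        band_size=k,
        overall_mean=overall,
        bottom_mean=float(bottom.mean()),
        top_mean=float(top.mean()),
        bottom_bound=float(bottom.max()),
        top_bound=float(top.min()),
    )


def weight_difference_distribution(
    tree_fit: StackingFit, forest_fit: StackingFit, m: int
) -> np.ndarray:
    """Per-tree (implied forest weight w_k/m) minus (direct tree weight).

    The two fits must describe the same trees in the same order; component
    ids are checked for alignment.
    """
    implied = implied_tree_weights(forest_fit, m)
    direct = np.asarray(tree_fit.weights, dtype=float)
    if implied.shape[0] != direct.shape[0]:
        raise ValueError("fits describe different numbers of trees")
    expanded = [sid for sid in forest_fit.col_component for _ in range(m)]
    tree_sources = [tid[0] for tid in tree_fit.col_component]
    if expanded != tree_sources:
        raise ValueError("component ids of the two fits are not aligned")
    return implied - direct


def _band_assignments(weights: np.ndarray) -> dict[str, np.ndarray]:
    n = weights.shape[0]
    k = n // 10
    order = np.argsort(weights, kind="stable")
    bands = {"0-100%": np.arange(n)}
    if k >= 1:
        bands["0-10%"] = order[:k]
        bands["90-100%"] = order[n - k:]
    return bands


def tree_structure_table(
    predictor: EnsemblePredictor,
    model: GenerativeModel,
    studies: dict[str, Study] | None = None,
    seed: int = 0,
    include_varimp: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tree metrics and weight-decile band summary for one fitted ensemble.

    Forest-level ensembles are first re-expressed tree by tree with implied
    weights.  Returns ``(per_tree, bands)``: one row per tree, and one row
    per band (bottom decile, top decile, overall) with the band's mean
    weight, mean true-feature split frequency, mean interaction-feature
    count and — when ``include_varimp`` is set and per-tree OOB data are
    available via ``studies`` — the proportion of permutation-importance
    mass on true features, computed from the band's trees.
    """
    tl = as_tree_level(predictor)
    trees = tl.components
    weights = tl.weights
    rows = []
    for t, w in zip(trees, weights):
        s = tree_structure_metrics(t, model, weight=w)
        rows.append(
            {
                "study_id": t.source_study,
                "tree_index": t.tree_id[1],
                "weight": s.weight,
                "freq_true_vars": s.freq_true_vars,
                "n_interaction_vars": s.n_interaction_vars,
            }
        )
    per_tree = pd.DataFrame(rows)

    diffs = None
    usable = None
    if include_varimp:
        if studies is None:
            raise ValueError("include_varimp requires the per-study training data")
        rng = np.random.default_rng(seed)
        diffs, skipped = _oob_mse_differences(trees, studies, rng, predictor.n_features)
        usable = np.setdiff1d(np.arange(len(trees)), np.asarray(skipped, dtype=int))

    band_rows = []
    for band, idx in _band_assignments(weights).items():
        entry = {
            "band": band,
            "mean_weight": float(weights[idx].mean()),
            "freq_true_vars": float(per_tree["freq_true_vars"].to_numpy()[idx].mean()),
            "n_interaction_vars": float(
                per_tree["n_interaction_vars"].to_numpy()[idx].mean()
            ),
        }
        if diffs is not None:
            pos = np.flatnonzero(np.isin(usable, idx))
            if pos.size >= 2:
                imp = _normalize_importance(diffs[pos])
                entry["prop_true_varimp"] = proportion_true_varimp(imp, model.true_idx)
            else:
                entry["prop_true_varimp"] = float("nan")
        band_rows.append(entry)
    order = {"90-100%": 0, "0-10%": 1, "0-100%": 2}
    bands = pd.DataFrame(band_rows).sort_values(
        "band", key=lambda s: s.map(order)
    ).reset_index(drop=True)
    return per_tree, bands
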