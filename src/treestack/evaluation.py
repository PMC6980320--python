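"""Scenario runners and scoring: RMSE / log loss, percent change versus the
Merged learner, heterogeneity sweeps and interaction-variance curves.

Each scenario iteration draws a fresh multi-study collection, fits all four
strategies on identical training data, and scores them on identical
validation studies.  Validation studies are scored separately and averaged
with equal study weight, so a large study cannot dominate the pooled score.
Summaries report the mean over iterations, its standard error, a 1.96 x SE
confidence half-width, and the percent change versus the Merged learner.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensembles import STRATEGIES, fit_all_strategies
from .stacking import StackingConfig
from .synthetic import (
    HeterogeneityProfile,
    ScenarioConfig,
    build_collection,
    generate_outcome,
    interaction_variance_share,
    perturb_coefficients,
    sample_features,
    draw_generative_model,
)

logger = logging.getLogger("treestack")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def rmse(predictions: np.ndarray, truth: np.ndarray) -> float:
    """Root mean squared error."""
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth differ in length")
    return float(np.sqrt(np.mean((predictions - truth) ** 2)))


def log_loss(probabilities: np.ndarray, truth: np.ndarray) -> float:
    """Negative mean Bernoulli log-likelihood of predicted probabilities."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and truth differ in length")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def percent_change_vs_merged(score: float, merged_score: float) -> float:
    """100 x (score - merged) / merged; negative means better than Merged."""
    if merged_score == 0:
        raise ValueError("percent change undefined for a zero Merged score")
    return 100.0 * (score - merged_score) / merged_score


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------


@dataclass
class ScenarioResult:
    """Per-iteration scores plus the aggregated summary of one scenario."""

    config: ScenarioConfig
    per_iteration: pd.DataFrame  # iteration, seed, strategy, study_id, score
    summary: pd.DataFrame  # strategy, mean, se, ci_halfwidth, pct_change_vs_merged
    n_failures: int = 0
    failures: list = field(default_factory=list)
    scenario_params: dict = field(default_factory=dict)


def _score_rows(fitted, collection, metric, iteration, seed):
    rows = []
    for strategy in STRATEGIES:
        ens = fitted[strategy]
        for vs in collection.validate_studies:
            pred = ens.predict(vs.features)
            rows.append(
                {
                    "iteration": iteration,
                    "seed": seed,
                    "strategy": strategy,
                    "study_id": vs.study_id,
                    "score": metric(pred, vs.outcome),
                }
            )
    return rows


def summarize_iterations(per_iteration: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-iteration pooled scores into the scenario summary."""
    pooled = (
        per_iteration.groupby(["iteration", "strategy"], as_index=False)["score"].mean()
    )
    summary = pooled.groupby("strategy")["score"].agg(["mean", "std", "count"]).reset_index()
    summary["se"] = summary["std"] / np.sqrt(summary["count"])
    summary["se"] = summary["se"].fillna(0.0)
    summary["ci_halfwidth"] = 1.96 * summary["se"]
    merged_mean = float(summary.loc[summary["strategy"] == "merged", "mean"].iloc[0])
    summary["pct_change_vs_merged"] = [
        percent_change_vs_merged(v, merged_mean) for v in summary["mean"]
    ]
    return summary[["strategy", "mean", "se", "ci_halfwidth", "pct_change_vs_merged"]]


def pooled_scores(per_iteration: pd.DataFrame) -> pd.DataFrame:
    """Per-iteration scores pooled over validation studies (equal study weight)."""
    return (
        per_iteration.groupby(["iteration", "strategy"], as_index=False)["score"]
        .mean()
        .pivot(index="iteration", columns="strategy", values="score")
    )


def run_scenario(
    config: ScenarioConfig,
    n_iterations: int | None = None,
    master_seed: int | None = None,
) -> ScenarioResult:
    """Run one scenario: fresh collection, four strategies, validation scores.

    Iterations are independently seeded from the master seed (so results do
    not depend on execution order); an iteration that raises is recorded as
    a failure and skipped.
    """
    n_iter = config.n_iterations if n_iterations is None else n_iterations
    seed = config.master_seed if master_seed is None else master_seed
    metric = log_loss if config.outcome_type == "binary" else rmse
    stacking_cfg = StackingConfig(**config.stacking) if config.stacking else StackingConfig()
    children = np.random.SeedSequence(seed).spawn(n_iter)
    rows = []
    failures = []
    for i, child in enumerate(children):
        coll_seed, fit_seed = (int(v % (2**31)) for v in child.generate_state(2))
        try:
            collection, _model = build_collection(config, coll_seed)
            fitted = fit_all_strategies(
                collection, m=config.m, mtry=config.mtry, stacking=stacking_cfg, seed=fit_seed
            )
            rows.extend(_score_rows(fitted, collection, metric, i, coll_seed))
            logger.info("scenario iteration %d done (seed=%d)", i, coll_seed)
        except Exception as exc:  # noqa: BLE001 - iteration isolation is the contract
            failures.append((i, repr(exc)))
            logger.warning("iteration %d failed: %r", i, exc)
    if not rows:
        raise RuntimeError(f"all {n_iter} iterations failed: {failures[:3]}")
    per_iteration = pd.DataFrame(rows)
    summary = summarize_iterations(per_iteration)
    return ScenarioResult(
        config=config,
        per_iteration=per_iteration,
        summary=summary,
        n_failures=len(failures),
        failures=failures,
    )


LOW_LEVEL = 0.25  # training low-group perturbation, held constant in sweeps


def run_heterogeneity_sweep(
    config: ScenarioConfig,
    levels,
    n_iterations: int | None = None,
    seed: int | None = None,
) -> list[ScenarioResult]:
    """One scenario per heterogeneity level.

    At each level ``l``: the high training group is perturbed at ``l``, the
    low group stays at 0.25, and validation studies sit at ``l / 2``.  All
    levels share the same iteration seeds (common random numbers), so level
    contrasts are paired — the same base models and feature draws, differing
    only in perturbation width — rather than confounded with simulation noise.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    base_seed = config.master_seed if seed is None else seed
    results = []
    for level in levels:
        het = HeterogeneityProfile(
            l_low=min(LOW_LEVEL, level),
            l_high=level,
            l_validate=level / 2.0,
            n_low_train=config.heterogeneity.n_low_train,
            interaction_scenario=config.heterogeneity.interaction_scenario,
        )
        cfg = dataclasses.replace(config, heterogeneity=het)
        res = run_scenario(cfg, n_iterations=n_iterations, master_seed=base_seed)
        res.scenario_params = {"l_high": level, "l_low": het.l_low, "l_validate": level / 2.0}
        results.append(res)
    return results


def sweep_summary(results: list[ScenarioResult]) -> pd.DataFrame:
    """Tidy table of per-strategy means across a sweep."""
    frames = []
    for res in results:
        df = res.summary.copy()
        for k, v in res.scenario_params.items():
            df[k] = v
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def interaction_variance_curve(
    config: ScenarioConfig,
    strengths,
    n_reps: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean percent of outcome variance explained by interactions, per strength.

    For each interaction strength, ``n_reps`` independent draws of (model,
    features, perturbed coefficients) are made at the scenario's baseline
    heterogeneity, and the empirical interaction variance share recorded.
    """
    scenario = config.heterogeneity.interaction_scenario
    if scenario == "none":
        scenario = "two_train_two_test"
    rows = []
    ss = np.random.SeedSequence(seed).spawn(len(list(strengths)))
    for s_val, child in zip(strengths, ss):
        rng = np.random.default_rng(child)
        shares = []
        for _ in range(n_reps):
            model = draw_generative_model(
                config.p, rng, interaction_scenario=scenario,
                interaction_strength=float(s_val), noise_sd=config.noise_sd,
            )
            X = sample_features(config.feature_source, config.n_per_study, config.p, rng)
            effects = perturb_coefficients(model, config.heterogeneity.l_high, rng)
            shares.append(interaction_variance_share(X, effects))
        rows.append(
            {
                "interaction_strength": float(s_val),
                "pct_variance_interactions": 100.0 * float(np.mean(shares)),
                "se": 100.0 * float(np.std(shares, ddof=1) / np.sqrt(n_reps)),
            }
        )
    return pd.DataFrame(rows)


def plot_sweep(results: list[ScenarioResult], path) -> None:
    """RMSE-vs-heterogeneity curves with 1.96 x SE ribbons (one line per strategy)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = sweep_summary(results)
    fig, ax = plt.subplots(figsize=(6, 4))
    for strategy, grp in df.groupby("strategy"):
        grp = grp.sort_values("l_high")
        ax.plot(grp["l_high"], grp["mean"], marker="o", label=strategy)
        ax.fill_between(
            grp["l_high"],
            grp["mean"] - grp["ci_halfwidth"],
            grp["mean"] + grp["ci_halfwidth"],
            alpha=0.2,
        )
    ax.set_xlabel("feature effect heterogeneity (l_high)")
    ax.set_ylabel("validation RMSE")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
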