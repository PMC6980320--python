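# treestack

Multi-study ensemble learning with tree-level stacking weights.

When several studies measure the same outcome and features — the canonical
example being gene-expression cohorts with a clinical endpoint — a predictor
trained on one study often fails to replicate on the others. A cross-study
learner (CSL) addresses this by training a single-study learner (SSL) on
each of the *K* training studies and combining them,

    ŷ(x) = b₀ + Σₖ wₖ ŷₖ(x),

with weights that reward *cross-study* prediction. `treestack` implements
and evaluates this architecture with random forests as the SSL, comparing
four strategies:

* **Merged** — one forest of *K·m* trees on the pooled training data;
* **Unweighted** — the *K* per-study forests averaged with equal weight 1/*K*;
* **Weighting Forests** — the *K* forests combined with stacking weights;
* **Weighting Trees** — the *K·m* individual trees extracted from those
  forests, each weighted directly.

The stacking weights solve a non-negative ridge regression of the stacked
true outcomes *Y* (length *N*, all training observations) on the stacked
prediction matrix *T* (*N × J*, one column per forest or per tree):

    min_{w ≥ 0, b₀}  ‖Y − b₀ − T w‖²  +  λ‖w‖²,

with λ chosen by 10-fold cross-validation over a 100-point log-spaced grid.
Weights are not normalized to sum to one. A forest weighted *wₖ* implicitly
gives each of its *m* trees weight *wₖ/m*; weighting trees directly lets the
ensemble up-weight the few trees that generalize across studies and shrink
the rest, which is where its advantage comes from.

The package also provides the simulation framework used to study the method
(multi-study collections with controlled feature-distribution and
feature-effect heterogeneity, optional interaction terms in the outcome
model) and tree-structure diagnostics (true-variable split frequencies,
interaction-variable counts, out-of-bag permutation importance, and
weight-decile summaries).

## Worked example

```python
import treestack as ts

cfg = ts.ScenarioConfig()          # K=10 train + V=5 validation studies,
                                   # n_k=100, p=100 features (10 true),
                                   # m=10 trees per forest, mtry=9
collection, model = ts.build_collection(cfg, iteration_seed=123)
fitted = ts.fit_all_strategies(collection, m=10, mtry=9, seed=7)

for strategy in ts.STRATEGIES:
    ens = fitted[strategy]
    vs = collection.validate_studies[0]
    print(strategy, len(ens.components),
          round(ts.rmse(ens.predict(vs.features), vs.outcome), 3))
```

prints

```
merged 1 5.761
unweighted 10 7.053
weighting_forests 10 5.14
weighting_trees 100 4.797
```

i.e. on this validation study the tree-weighted ensemble (100 weighted
trees) reaches RMSE 4.80 versus 5.76 for the merged forest, with the
forest-weighted ensemble in between and the unweighted average worst.
Averaged over 20 simulation iterations of the baseline scenario the same
ordering holds with tight confidence bands:

```python
res = ts.run_scenario(cfg, n_iterations=20, master_seed=11)
print(res.summary)
#          strategy   mean     se   ci_halfwidth  pct_change_vs_merged
#            merged  6.698  0.244          0.478                 0.000
#        unweighted  7.986  0.292          0.572                19.225
# weighting_forests  6.125  0.221          0.433                -8.558
#   weighting_trees  5.666  0.204          0.400               -15.407
```

`pct_change_vs_merged` is 100·(RMSE − RMSE_merged)/RMSE_merged, so
Weighting Trees improves on the Merged learner by about 15% here while the
Unweighted average is 19% worse.

A thin CLI wraps the same functions: `treestack simulate | fit | predict |
evaluate | sweep | diagnose` (see `treestack --help`); scenario files are
YAML renderings of `ScenarioConfig`.

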