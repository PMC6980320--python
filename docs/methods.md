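# Methods

## The model

`treestack` studies cross-study ensembling of random forests. Given K
training studies with a shared ordered feature space, a single-study learner
(SSL) — a random forest of m trees — is trained on each study. A cross-study
learner combines SSL predictions linearly,

    ŷ(x) = b₀ + Σⱼ wⱼ ŷⱼ(x),

where the components j are either the K whole forests ("Weighting Forests")
or the K·m individual trees extracted from them ("Weighting Trees"). Two
benchmarks complete the comparison: the Merged forest (K·m trees trained on
the pooled rows of all training studies, weight 1, intercept 0) and the
Unweighted average of the K forests (weights 1/K, intercept 0). All four
strategies share one prediction contract and are always evaluated on
identical validation data.

## Stacking weights

The weights are fitted by stacked regression across studies: the stack
matrix T (N × J) holds each component's predictions on every training
observation (studies stacked in collection order, N = Σ nₖ), Y stacks the
true outcomes in the same row order, and the weights solve

    min_{w ≥ 0, b₀}  ‖Y − b₀·1 − T·w‖² + λ‖w‖²       (ridge, default)

with the intercept unpenalized and unconstrained. The constrained form
(‖w‖² ≤ c) is equivalent by Lagrangian duality; the penalized form is solved
directly. Non-negativity is imposed with a closed feasible set (w ≥ 0):
zero weights are meaningful and must be attainable. Weights are *not*
normalized to sum to one. A component's predictions on its own source study
enter T as ordinary refit predictions; an `own_study="oob"` switch replaces
a forest's own-study column with its out-of-bag prediction as a guard
against stacking overfit (a single tree's prediction does not depend on bag
membership, so the switch leaves tree-level columns unchanged — documented
rather than simulated around).

Solver: columns of T are scaled to unit standard deviation (weights are
back-transformed; non-negativity survives positive scaling) and, when an
intercept is fitted, both sides are centred, which reduces the problem to
a non-negative quadratic program on the Gram matrix G = Tᶜ′Tᶜ. For each λ
the program is solved exactly via a Cholesky factorization of G + λI and
Lawson–Hanson NNLS. λ is selected by cross-validated squared error
(10 folds over observations by default; study-level folds optional) on a
100-point descending log grid anchored at max|Tᶜ′Yᶜ| and spanning six
decades. This Gram-space path costs milliseconds per (fold, λ) even at
J = 100 tree columns. A non-negative lasso variant (the L1 term is linear
on the feasible set, so the same NNLS machinery applies with a shifted
linear term) and a no-intercept variant sit behind config switches; ridge
with intercept is the default because shrinking without zeroing keeps
weakly cross-validating components available for genuinely new studies.
Degenerate inputs: an all-constant Y yields w = 0 and intercept mean(Y);
an all-constant column of T is dropped with a warning and reported with
weight 0.

A forest-level fit implies tree-level weights wₖ/m (each of the m trees in
forest k inherits an equal share). This identity is exact: the forest-level
ensemble and the implied tree-level ensemble produce identical predictions,
which the tests assert to 1e-10.

## Forests

Forests are scikit-learn `RandomForestRegressor`/`Classifier` with
m = 10 trees per forest and mtry = 9 candidate features per split as the
main-analysis defaults (both configurable; mtry = 9 at p = 100 is treated
as a deliberate setting, not a √p or p/3 convention), minimum node size at
the backing learner's default. m = 10 favours many cheap scenario
iterations; ensemble orderings are conserved as forests grow. The Merged
learner always gets K·m trees so every strategy deploys the same total
number of trees. Per-tree out-of-bag (OOB) indices are recorded at training
time; bootstrap can be disabled as a test hook for exact-recovery checks.
For binary outcomes trees predict class-1 probabilities, forests average
them, stacking regresses the 0/1 outcome on stacked probabilities with the
same squared-error objective (the minimal faithful choice absent a stated
link), and ensemble outputs are clipped to [1e-15, 1 − 1e-15] for log-loss
evaluation.

## The simulation framework

Each scenario iteration draws a fresh generative model: 10 of p = 100
features are outcome-associated ("true"), with coefficients uniform on
[−5, −0.5] ∪ [0.5, 5]. Between-study *feature-effect* heterogeneity is a
per-study uniform perturbation of the coefficient vector on [c − l, c + l]
(one draw per study): 5 training studies at l_low = 0.25, 5 at l_high
(baseline 1), validation studies at an intermediate level defaulting to
l_high/2 (0.5 at baseline; an explicit `l_validate` — e.g. 0.4 — overrides
the rule). *Feature-distribution* heterogeneity comes from
independent per-study feature draws; `repeated_single_study` mode reuses
one matrix for all K training studies to switch it off, and `pseudo_split`
mode splits one source matrix into 5 equal disjoint parts (4 train, 1
validate; remainder rows go to the last part) to emulate sub-sampling a
single large cohort.

Features default to block-correlated Gaussians (blocks of 10, within-block
ρ = 0.3, unit variance) — a synthetic stand-in for the correlated structure
of expression data; a resampling source that draws rows with replacement
from a user-supplied matrix is available when real feature vectors exist.
What the generator does **not** emulate: heavy-tailed and platform-specific
expression distributions, study-specific covariance structure, batch
effects, and censored survival outcomes. Passing tests therefore establish
the method's behaviour under controlled effect/distribution heterogeneity,
not its performance on any particular real cohort collection.

Outcomes are linear in the true features plus Gaussian noise with sd 1
(the signal-to-noise knob; configurable). Interaction scenarios place
pairwise-product terms among 3 of the 10 true features in a stated number
of studies — (2 train, 2 validate) or (6 train, 2 validate) — with all 3
pairwise products of the chosen triple entering at coefficient s × random
sign. Interaction coefficients are perturbed like main effects in studies
that carry them. A scenario with interaction strength s = 0 has *no*
interaction structure: otherwise perturbation of zero coefficients would
manufacture interaction effects, and the interaction-variance share would
not vanish at s = 0. The share itself is computed empirically as
Var(interaction component) / [Var(linear predictor) + noise variance].
Per-study sample size defaults to 100 (within the 42–510 range typical of
the motivating cohorts). Binary outcomes use a logistic link on the linear
predictor divided by a configurable scale.

Seeding: a master seed spawns independent per-iteration streams
(numpy `SeedSequence`), and within an iteration separate substreams for the
model draw, study assignment, per-study features/effects and forest
training, so any single study or forest is reproducible in isolation and
iterations are order-independent.

## Evaluation

Continuous outcomes are scored by RMSE, binary by log loss; validation
studies are scored separately and averaged with equal study weight (so a
large validation study cannot dominate). Scenario summaries report the
mean over iterations, its standard error, 1.96 × SE confidence half-widths,
and percent change versus Merged, 100·(score − merged)/merged. Default
scenario size is 20 iterations (100 to match larger studies of the method);
per-iteration scores are persisted so summaries can be audited against
them. The heterogeneity sweep holds l_low at 0.25 (capped by the level),
sets l_validate = l_high/2, and reuses the same iteration seeds at every
level (common random numbers): level contrasts are then paired — identical
base models and feature draws, differing only in perturbation width — so
the level effect is not confounded with simulation noise. Raw means are
reported; any smoothing is plotting-only.

## Diagnostics

For each tree: `freq_true_vars` is the fraction of internal split nodes
whose split feature is true (the per-split-node reading, which yields
values in [0, 1]; the distinct-variable reading is a known alternative),
and `n_interaction_vars` counts distinct interaction-involved features
among its split features. Permutation importance follows the OOB recipe:
per tree, the OOB MSE is recorded before and after permuting each feature
column; the per-feature differences are averaged over trees and normalized
by their standard deviation. Features a tree never splits on contribute an
exact zero difference (permuting them cannot change that tree's
predictions), features with zero spread keep their raw mean, trees with an
empty OOB set are skipped with a warning. For importance *proportions*,
negative importances are floored at zero first so the true-feature share
lies in [0, 1]. Weight-decile summaries band the sorted tree-level weights
(stable sort, ties broken by component index) into bottom 10%, top 10% and
overall; with fewer than 10 weights only the overall band is reported.
Band means necessarily satisfy bottom ≤ overall ≤ top. The
Weighting-Forests-minus-Weighting-Trees per-tree weight differences are
computed after an explicit component-id alignment check.

## Numerical choices and limitations

* Exactness claims (forest ≡ mean of trees; forest-level ≡ implied
  tree-level) hold to floating tolerance (1e-10 in tests) because both
  sides are the same linear combination evaluated in different orders.
* The QP solver is exact up to Cholesky/NNLS conditioning; tests compare
  its objective against an independent bound-constrained L-BFGS-B oracle
  on random instances (observed agreement ~1e-15 relative, asserted at
  1e-6).
* Directional claims (Weighting Trees < Weighting Forests < Unweighted;
  RMSE rising and strategy spread shrinking with heterogeneity; top-decile
  trees structurally richer than bottom-decile ones) are asserted at 20
  iterations of the main-analysis scale (K=10, V=5, nₖ=100, p=100, m=10),
  a problem size chosen to keep a full run in minutes on one CPU; the
  paired one-sided test for trees vs forests is reported with its p-value.
* Known limitations: tree-level stacking at J = K·m columns relies on the
  ridge penalty for stability when trees within a forest are highly
  correlated; the binary-outcome path stacks probabilities with a
  squared-error objective rather than a proper scoring rule; and the
  synthetic feature generator understates the covariance complexity of
  real expression data, which tends to *understate* the advantage of
  replicability weighting observed on real cohorts.
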