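"""Simulation of multi-study datasets with controlled between-study heterogeneity.

The generator emulates a gene-expression-like setting: a collection of
studies that share one ordered feature space, an outcome driven by a sparse
linear model on 10 "true" features, and two distinct sources of
between-study heterogeneity:

* **feature distribution heterogeneity** — studies draw their feature
  matrices independently (or, in ``repeated_single_study`` mode, share one
  matrix so this source is switched off);
* **feature effect heterogeneity** — each study perturbs the base
  coefficient vector ``c`` by an independent uniform draw on
  ``[c - l, c + l]``, where ``l`` is the study's heterogeneity level.

Training studies split into a low-heterogeneity and a high-heterogeneity
group; validation studies sit at an intermediate level (half the high
level by default).  Optionally a subset of studies carries pairwise
interaction terms between 3 of the 10 true features.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("treestack")

N_TRUE = 10
N_INTERACTION_VARS = 3
COEF_LOW, COEF_HIGH = 0.5, 5.0

#: interaction scenario -> (number of train studies, number of validation
#: studies) whose outcome model includes the interaction terms
INTERACTION_PLACEMENT = {
    "none": (0, 0),
    "two_train_two_test": (2, 2),
    "six_train_two_test": (6, 2),
}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Study:
    """One study: a feature matrix, an outcome vector and a train/validate role."""

    study_id: str
    features: np.ndarray  # (n_k, p)
    outcome: np.ndarray  # (n_k,)
    role: str = "train"  # "train" | "validate"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.outcome.shape[0]:
            raise ValueError("features and outcome disagree on sample count")
        if self.features.shape[0] < 2:
            raise ValueError("a study needs at least 2 samples")
        if np.isnan(self.features).any() or np.isnan(self.outcome).any():
            raise ValueError("missing values are not allowed")
        if self.role not in ("train", "validate"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]


@dataclass
class StudyCollection:
    """An ordered list of studies sharing a feature space."""

    studies: list[Study]

    def __post_init__(self) -> None:
        ps = {s.p for s in self.studies}
        if len(ps) > 1:
            raise ValueError(f"feature dimension differs across studies: {sorted(ps)}")
        if self.K < 1:
            raise ValueError("at least one training study is required")

    @property
    def train_studies(self) -> list[Study]:
        return [s for s in self.studies if s.role == "train"]

    @property
    def validate_studies(self) -> list[Study]:
        return [s for s in self.studies if s.role == "validate"]

    @property
    def K(self) -> int:
        return len(self.train_studies)

    @property
    def V(self) -> int:
        return len(self.validate_studies)

    @property
    def p(self) -> int:
        return self.studies[0].p

    def get(self, study_id: str) -> Study:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)


@dataclass
class StudyEffects:
    """The study-specific (perturbed) outcome model for one study.

    Self-contained: carries everything ``generate_outcome`` needs.
    """

    true_idx: np.ndarray
    coefficients: np.ndarray
    interaction_pairs: tuple[tuple[int, int], ...]
    interaction_coefficients: np.ndarray
    heterogeneity: float
    has_interactions: bool
    noise_sd: float = 1.0
    outcome_type: str = "continuous"
    binary_scale: float = 1.0


@dataclass
class GenerativeModel:
    """The sparse linear (plus optional interaction) data-generating model.

    ``true_idx`` holds the 10 outcome-associated feature indices, with base
    coefficients ``coefficients`` whose magnitudes lie in [0.5, 5].  When
    interactions are enabled, ``interaction_idx`` names 3 of the true
    features and each of their 3 pairwise products enters the linear
    predictor with coefficient ``interaction_strength`` times a random sign.
    ``study_effects`` is filled by :func:`build_collection` with the
    per-study perturbed models.
    """

    p: int
    true_idx: np.ndarray
    coefficients: np.ndarray
    interaction_idx: np.ndarray
    interaction_pairs: tuple[tuple[int, int], ...]
    interaction_coefficients: np.ndarray
    interaction_strength: float = 0.0
    noise_sd: float = 1.0
    outcome_type: str = "continuous"
    binary_scale: float = 1.0
    study_effects: dict[str, StudyEffects] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_idx = np.asarray(self.true_idx, dtype=int)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.interaction_idx = np.asarray(self.interaction_idx, dtype=int)
        self.interaction_coefficients = np.asarray(
            self.interaction_coefficients, dtype=float
        )
        mags = np.abs(self.coefficients)
        if np.any(mags < COEF_LOW - 1e-12) or np.any(mags > COEF_HIGH + 1e-12):
            raise ValueError("base coefficient magnitudes must lie in [0.5, 5]")
        if self.interaction_idx.size not in (0, N_INTERACTION_VARS):
            raise ValueError("interaction_idx must hold 0 or 3 features")
        if not set(self.interaction_idx).issubset(set(self.true_idx)):
            raise ValueError("interaction features must be true features")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")

    def base_effects(self, with_interactions: bool = True) -> StudyEffects:
        has = with_interactions and self.interaction_idx.size > 0
        return StudyEffects(
            true_idx=self.true_idx,
            coefficients=self.coefficients.copy(),
            interaction_pairs=self.interaction_pairs,
            interaction_coefficients=(
                self.interaction_coefficients.copy()
                if has
                else np.zeros(len(self.interaction_pairs))
            ),
            heterogeneity=0.0,
            has_interactions=has,
            noise_sd=self.noise_sd,
            outcome_type=self.outcome_type,
            binary_scale=self.binary_scale,
        )


@dataclass
class HeterogeneityProfile:
    """Perturbation levels for the train / validation studies.

    ``l_low``/``l_high`` are the two training levels; ``l_validate``
    defaults to half of ``l_high``.  ``n_low_train`` defaults to half the
    training studies (remainder to the high group).
    """

    l_low: float = 0.25
    l_high: float = 1.0
    l_validate: float | None = None
    n_low_train: int | None = None
    interaction_scenario: str = "none"

    def __post_init__(self) -> None:
        if self.l_low < 0 or self.l_high < 0:
            raise ValueError("heterogeneity levels must be non-negative")
        if self.l_low > self.l_high:
            raise ValueError("l_low must not exceed l_high")
        if self.l_validate is not None and self.l_validate < 0:
            raise ValueError("l_validate must be non-negative")
        if self.interaction_scenario not in INTERACTION_PLACEMENT:
            raise ValueError(
                f"unknown interaction_scenario {self.interaction_scenario!r}"
            )

    def resolve(self, K: int) -> tuple[float, float, float, int, int]:
        """Concrete (l_low, l_high, l_validate, n_low, n_high) for K train studies."""
        l_val = self.l_high / 2.0 if self.l_validate is None else self.l_validate
        n_low = K // 2 if self.n_low_train is None else self.n_low_train
        if not 0 <= n_low <= K:
            raise ValueError("n_low_train must lie in [0, K]")
        return self.l_low, self.l_high, l_val, n_low, K - n_low


@dataclass(frozen=True)
class MVNSpec:
    """Block-correlated multivariate-normal feature source.

    Unit-variance features in consecutive blocks of ``block_size`` with
    within-block correlation ``rho``; blocks are independent.  A crude but
    serviceable stand-in for the correlated structure of expression data.
    """

    block_size: int = 10
    rho: float = 0.3
    kind: str = "synthetic_mvn"


@dataclass(frozen=True)
class ResampleSpec:
    """Feature source that resamples rows (with replacement) from a matrix."""

    matrix: np.ndarray
    kind: str = "resample_matrix"


FeatureSource = MVNSpec | ResampleSpec


@dataclass
class ScenarioConfig:
    """Full configuration of one simulation scenario."""

    mode: str = "multi_study"  # multi_study | repeated_single_study | pseudo_split
    K: int = 10
    V: int = 5
    n_per_study: int = 100
    p: int = 100
    feature_source: FeatureSource = field(default_factory=MVNSpec)
    interaction_strength: float = 1.0
    noise_sd: float = 1.0
    outcome_type: str = "continuous"
    binary_scale: float = 1.0
    heterogeneity: HeterogeneityProfile = field(default_factory=HeterogeneityProfile)
    n_iterations: int = 20
    master_seed: int = 0
    m: int = 10
    mtry: int = 9
    stacking: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("multi_study", "repeated_single_study", "pseudo_split"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.V < 1:
            raise ValueError("V must be at least 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be at least 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        src = d.pop("feature_source")
        if isinstance(self.feature_source, ResampleSpec):
            src["matrix"] = np.asarray(src["matrix"]).tolist()
        d["feature_source"] = src
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        src = d.get("feature_source")
        if isinstance(src, dict):
            src = dict(src)
            kind = src.pop("kind", "synthetic_mvn")
            if kind == "synthetic_mvn":
                d["feature_source"] = MVNSpec(**src)
            elif kind == "resample_matrix":
                d["feature_source"] = ResampleSpec(
                    matrix=np.asarray(src["matrix"], dtype=float)
                )
            else:
                raise ValueError(f"unknown feature source kind {kind!r}")
        het = d.get("heterogeneity")
        if isinstance(het, dict):
            d["heterogeneity"] = HeterogeneityProfile(**het)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def sample_features(source: FeatureSource, n: int, p: int, seed) -> np.ndarray:
    """Draw an n x p feature matrix from the given source.

    ``synthetic_mvn`` draws block-correlated standard normals.  ``resample``
    draws rows with replacement from the source matrix, restricted to ``p``
    randomly chosen columns (kept in ascending order, so with ``p`` equal to
    the source width each output row is exactly a source row).
    """
    rng = _rng(seed)
    if n < 1 or p < 1:
        raise ValueError("n and p must be positive")
    if isinstance(source, MVNSpec):
        b = source.block_size
        if b < 1:
            raise ValueError("block_size must be positive")
        # positive definiteness of an equicorrelated block of size b
        if not (-1.0 / max(b - 1, 1) < source.rho < 1.0) and not (
            b == 1 and abs(source.rho) < 1
        ):
            raise ValueError(
                f"rho={source.rho} does not give a positive-definite "
                f"covariance for block size {b}"
            )
        X = np.empty((n, p))
        for start in range(0, p, b):
            stop = min(start + b, p)
            width = stop - start
            cov = np.full((width, width), source.rho)
            np.fill_diagonal(cov, 1.0)
            L = np.linalg.cholesky(cov)
            X[:, start:stop] = rng.standard_normal((n, width)) @ L.T
        return X
    if isinstance(source, ResampleSpec):
        src = np.asarray(source.matrix, dtype=float)
        if src.ndim != 2:
            raise ValueError("resample source must be a 2-D matrix")
        if p > src.shape[1]:
            raise ValueError(
                f"requested p={p} exceeds source column count {src.shape[1]}"
            )
        rows = rng.integers(0, src.shape[0], size=n)
        cols = np.sort(rng.choice(src.shape[1], size=p, replace=False))
        return src[np.ix_(rows, cols)]
    raise TypeError(f"unknown feature source {type(source).__name__}")


def draw_generative_model(
    p: int,
    seed,
    interaction_scenario: str = "none",
    interaction_strength: float = 1.0,
    noise_sd: float = 1.0,
    outcome_type: str = "continuous",
    binary_scale: float = 1.0,
) -> GenerativeModel:
    """Draw a sparse linear data-generating model on ``p`` features.

    10 distinct true features are chosen uniformly; each base coefficient is
    uniform on [-5, -0.5] or [0.5, 5] with equal probability.  When the
    interaction scenario is not ``none``, 3 of the true features are chosen
    and each of their 3 pairwise products gets coefficient
    ``interaction_strength`` times an independent random sign.
    """
    rng = _rng(seed)
    if p < N_TRUE:
        raise ValueError(f"p must be at least {N_TRUE}")
    if interaction_scenario not in INTERACTION_PLACEMENT:
        raise ValueError(f"unknown interaction_scenario {interaction_scenario!r}")
    if interaction_strength < 0:
        raise ValueError("interaction_strength must be non-negative")
    true_idx = np.sort(rng.choice(p, size=N_TRUE, replace=False))
    signs = rng.choice([-1.0, 1.0], size=N_TRUE)
    coefficients = signs * rng.uniform(COEF_LOW, COEF_HIGH, size=N_TRUE)
    # zero-strength interaction terms are no interaction terms: this keeps the
    # strength axis anchored at an exactly-zero interaction variance share
    if interaction_scenario != "none" and interaction_strength > 0:
        interaction_idx = np.sort(
            rng.choice(true_idx, size=N_INTERACTION_VARS, replace=False)
        )
        pairs = tuple(itertools.combinations(interaction_idx.tolist(), 2))
        inter_signs = rng.choice([-1.0, 1.0], size=len(pairs))
        inter_coefs = interaction_strength * inter_signs
    else:
        interaction_idx = np.array([], dtype=int)
        pairs = ()
        inter_coefs = np.array([])
    return GenerativeModel(
        p=p,
        true_idx=true_idx,
        coefficients=coefficients,
        interaction_idx=interaction_idx,
        interaction_pairs=pairs,
        interaction_coefficients=inter_coefs,
        interaction_strength=interaction_strength,
        noise_sd=noise_sd,
        outcome_type=outcome_type,
        binary_scale=binary_scale,
    )


def perturb_coefficients(
    model: GenerativeModel,
    l: float,
    seed,
    with_interactions: bool = True,
) -> StudyEffects:
    """One study's perturbed model: each coefficient uniform on [c - l, c + l].

    Interaction coefficients (when the study carries interactions) are
    perturbed the same way.  One draw per study, shared by all its samples.
    """
    if l < 0:
        raise ValueError("heterogeneity level l must be non-negative")
    rng = _rng(seed)
    coefs = rng.uniform(model.coefficients - l, model.coefficients + l)
    has = with_interactions and model.interaction_idx.size > 0
    if has:
        inter = rng.uniform(
            model.interaction_coefficients - l, model.interaction_coefficients + l
        )
    else:
        inter = np.zeros(len(model.interaction_pairs))
    return StudyEffects(
        true_idx=model.true_idx,
        coefficients=coefs,
        interaction_pairs=model.interaction_pairs,
        interaction_coefficients=inter,
        heterogeneity=l,
        has_interactions=has,
        noise_sd=model.noise_sd,
        outcome_type=model.outcome_type,
        binary_scale=model.binary_scale,
    )


def _linear_predictor(X: np.ndarray, effects: StudyEffects) -> tuple[np.ndarray, np.ndarray]:
    """(main-effect component, interaction component) of the linear predictor."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] <= int(effects.true_idx.max()):
        raise ValueError("feature matrix too narrow for the generative model")
    main = X[:, effects.true_idx] @ effects.coefficients
    inter = np.zeros(X.shape[0])
    if effects.has_interactions:
        for (a, b), g in zip(effects.interaction_pairs, effects.interaction_coefficients):
            inter += g * X[:, a] * X[:, b]
    return main, inter


def generate_outcome(X: np.ndarray, effects: StudyEffects, seed=None) -> np.ndarray:
    """Generate the outcome vector for one study from its perturbed model.

    Continuous: linear predictor plus Gaussian noise with sd ``noise_sd``.
    Binary: Bernoulli with success probability
    ``logistic(linear predictor / binary_scale)``.
    """
    rng = _rng(seed)
    main, inter = _linear_predictor(X, effects)
    lp = main + inter
    if effects.outcome_type == "binary":
        from scipy.special import expit

        prob = expit(lp / effects.binary_scale)
        return rng.binomial(1, prob).astype(float)
    y = lp
    if effects.noise_sd > 0:
        y = y + rng.normal(0.0, effects.noise_sd, size=lp.shape[0])
    return y


def interaction_variance_share(X: np.ndarray, effects: StudyEffects) -> float:
    """Fraction of outcome variance attributed to the interaction terms.

    Computed as Var(interaction component) / [Var(full linear predictor)
    + noise variance], with the variances taken empirically over the rows
    of ``X``.  Exactly 0 when no interaction terms are present.
    """
    main, inter = _linear_predictor(X, effects)
    v_inter = float(np.var(inter))
    if v_inter == 0.0:
        return 0.0
    total = float(np.var(main + inter)) + effects.noise_sd**2
    return v_inter / total if total > 0 else 0.0


def build_collection(
    config: ScenarioConfig, iteration_seed: int
) -> tuple[StudyCollection, GenerativeModel]:
    """Generate one multi-study collection under the scenario configuration.

    Returns the collection and the generative model whose ``study_effects``
    maps each study id to its perturbed coefficient vector.
    """
    ss = np.random.SeedSequence(iteration_seed)
    model_ss, assign_ss, data_ss = ss.spawn(3)
    model_rng = np.random.default_rng(model_ss)
    assign_rng = np.random.default_rng(assign_ss)

    het = config.heterogeneity
    model = draw_generative_model(
        config.p,
        model_rng,
        interaction_scenario=het.interaction_scenario,
        interaction_strength=config.interaction_strength,
        noise_sd=config.noise_sd,
        outcome_type=config.outcome_type,
        binary_scale=config.binary_scale,
    )

    if config.mode == "pseudo_split":
        return _build_pseudo_split(config, model, assign_rng, data_ss)

    K, V = config.K, config.V
    l_low, l_high, l_val, n_low, n_high = het.resolve(K)
    levels = np.concatenate([np.full(n_low, l_low), np.full(n_high, l_high)])
    levels = assign_rng.permutation(levels)
    n_int_train, n_int_val = INTERACTION_PLACEMENT[het.interaction_scenario]
    if n_int_train > K or n_int_val > V:
        raise ValueError("interaction scenario places interactions in more studies than exist")
    int_train = set(assign_rng.choice(K, size=n_int_train, replace=False).tolist())
    int_val = set(assign_rng.choice(V, size=n_int_val, replace=False).tolist())

    children = data_ss.spawn(2 * (K + V) + 1)
    shared_X = None
    if config.mode == "repeated_single_study":
        shared_X = sample_features(
            config.feature_source, config.n_per_study, config.p, children[-1]
        )

    studies: list[Study] = []
    for k in range(K + V):
        is_train = k < K
        sid = f"train_{k:02d}" if is_train else f"validate_{k - K:02d}"
        role = "train" if is_train else "validate"
        feat_seed, eff_seed = children[2 * k], children[2 * k + 1]
        if is_train and shared_X is not None:
            X = shared_X.copy()
        else:
            X = sample_features(config.feature_source, config.n_per_study, config.p, feat_seed)
        level = levels[k] if is_train else l_val
        with_inter = (k in int_train) if is_train else ((k - K) in int_val)
        eff_rng = np.random.default_rng(eff_seed)
        effects = perturb_coefficients(model, level, eff_rng, with_interactions=with_inter)
        y = generate_outcome(X, effects, eff_rng)
        model.study_effects[sid] = effects
        studies.append(Study(sid, X, y, role=role))
    collection = StudyCollection(studies)
    logger.debug(
        "built collection: mode=%s K=%d V=%d p=%d seed=%d",
        config.mode, collection.K, collection.V, collection.p, iteration_seed,
    )
    return collection, model


N_PSEUDO_PARTS = 5


def _build_pseudo_split(
    config: ScenarioConfig,
    model: GenerativeModel,
    assign_rng: np.random.Generator,
    data_ss: np.random.SeedSequence,
) -> tuple[StudyCollection, GenerativeModel]:
    """Split one source matrix into 5 equal parts: 4 train, 1 validate.

    When the source rows do not divide evenly, the last (validation) part
    takes the remainder.
    """
    children = data_ss.spawn(N_PSEUDO_PARTS + 1)
    if isinstance(config.feature_source, ResampleSpec):
        src = np.asarray(config.feature_source.matrix, dtype=float)
        if config.p > src.shape[1]:
            raise ValueError("p exceeds the pseudo-split source column count")
        cols = np.sort(assign_rng.choice(src.shape[1], size=config.p, replace=False))
        X_all = src[:, cols]
    else:
        X_all = sample_features(
            config.feature_source,
            N_PSEUDO_PARTS * config.n_per_study,
            config.p,
            children[-1],
        )
    n_total = X_all.shape[0]
    if n_total < 2 * N_PSEUDO_PARTS:
        raise ValueError("pseudo_split source has too few rows")
    order = assign_rng.permutation(n_total)
    part_size = n_total // N_PSEUDO_PARTS
    K = N_PSEUDO_PARTS - 1
    het = config.heterogeneity
    l_low, l_high, l_val, n_low, n_high = het.resolve(K)
    levels = assign_rng.permutation(
        np.concatenate([np.full(n_low, l_low), np.full(n_high, l_high)])
    )
    n_int_train, n_int_val = INTERACTION_PLACEMENT[het.interaction_scenario]
    n_int_train = min(n_int_train, K)
    n_int_val = min(n_int_val, 1)
    int_train = set(assign_rng.choice(K, size=n_int_train, replace=False).tolist())

    studies: list[Study] = []
    for k in range(N_PSEUDO_PARTS):
        is_train = k < K
        lo = k * part_size
        hi = (k + 1) * part_size if is_train else n_total
        X = X_all[order[lo:hi]]
        sid = f"train_{k:02d}" if is_train else "validate_00"
        level = levels[k] if is_train else l_val
        with_inter = (k in int_train) if is_train else n_int_val > 0
        eff_rng = np.random.default_rng(children[k])
        effects = perturb_coefficients(model, level, eff_rng, with_interactions=with_inter)
        y = generate_outcome(X, effects, eff_rng)
        model.study_effects[sid] = effects
        studies.append(Study(sid, X, y, role="train" if is_train else "validate"))
    return StudyCollection(studies), model


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def feature_names(p: int) -> list[str]:
    return [f"f{j:03d}" for j in range(p)]


def write_collection(collection: StudyCollection, outdir, seed: int | None = None) -> None:
    """Write one CSV per study (features + outcome + study_id) and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "studies": []}
    cols = feature_names(collection.p)
    for s in collection.studies:
        df = pd.DataFrame(s.features, columns=cols)
        df["outcome"] = s.outcome
        df["study_id"] = s.study_id
        df.to_csv(outdir / f"{s.study_id}.csv", index=False)
        manifest["studies"].append({"study_id": s.study_id, "role": s.role, "n": s.n})
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_collection(indir) -> StudyCollection:
    """Read a collection written by :func:`write_collection`."""
    indir = Path(indir)
    with open(indir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    studies = []
    for entry in manifest["studies"]:
        df = pd.read_csv(indir / f"{entry['study_id']}.csv")
        X = df.drop(columns=["outcome", "study_id"]).to_numpy(dtype=float)
        studies.append(
            Study(entry["study_id"], X, df["outcome"].to_numpy(dtype=float), role=entry["role"])
        )
    return StudyCollection(studies)
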