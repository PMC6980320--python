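"""Generator contracts: feature sources, coefficient draws, perturbation,
outcome construction and collection assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import treestack as ts
from treestack.synthetic import INTERACTION_PLACEMENT


class TestSampleFeatures:
    def test_independent_mvn_has_near_zero_correlations(self):
        X = ts.sample_features(ts.MVNSpec(block_size=5, rho=0.0), 2000, 10, seed=1)
        corr = np.corrcoef(X, rowvar=False)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.max(np.abs(off)) < 0.08

    def test_block_correlation_matches_spec(self):
        X = ts.sample_features(ts.MVNSpec(block_size=5, rho=0.6), 2000, 10, seed=2)
        corr = np.corrcoef(X, rowvar=False)
        within = []
        for start in (0, 5):
            block = corr[start:start + 5, start:start + 5]
            within.extend(block[~np.eye(5, dtype=bool)])
        assert abs(np.mean(within) - 0.6) < 0.05

    def test_resample_rows_come_from_source(self, rng):
        src = rng.normal(size=(4, 10))
        X = ts.sample_features(ts.ResampleSpec(matrix=src), 25, 10, seed=3)
        for row in X:
            assert any(np.array_equal(row, s) for s in src)

    def test_resample_p_too_large_raises(self, rng):
        src = rng.normal(size=(4, 10))
        with pytest.raises(ValueError, match="exceeds"):
            ts.sample_features(ts.ResampleSpec(matrix=src), 5, 11, seed=0)

    def test_invalid_rho_raises(self):
        with pytest.raises(ValueError, match="positive-definite"):
            ts.sample_features(ts.MVNSpec(block_size=5, rho=-0.5), 10, 10, seed=0)


class TestGenerativeModel:
    def test_coefficient_magnitudes_in_band(self):
        for seed in range(30):
            model = ts.draw_generative_model(100, seed)
            mags = np.abs(model.coefficients)
            assert np.all(mags >= 0.5) and np.all(mags <= 5.0)
            assert len(set(model.true_idx.tolist())) == 10

    def test_no_interactions_when_disabled(self):
        model = ts.draw_generative_model(50, 4, interaction_scenario="none")
        assert model.interaction_idx.size == 0
        assert model.interaction_pairs == ()

    def test_interaction_structure(self):
        model = ts.draw_generative_model(
            50, 4, interaction_scenario="two_train_two_test", interaction_strength=2.0
        )
        assert model.interaction_idx.size == 3
        assert set(model.interaction_idx).issubset(set(model.true_idx))
        assert len(model.interaction_pairs) == 3
        assert np.all(np.abs(model.interaction_coefficients) == 2.0)

    def test_coefficient_sign_symmetry(self):
        rng = np.random.default_rng(7)
        signs = [ts.draw_generative_model(10, rng).coefficients[0] > 0 for _ in range(10_000)]
        assert abs(np.mean(signs) - 0.5) < 0.02

    def test_p_below_ten_rejected(self):
        with pytest.raises(ValueError):
            ts.draw_generative_model(9, 0)


class TestPerturbation:
    def test_zero_level_is_identity(self):
        model = ts.draw_generative_model(20, 1)
        eff = ts.perturb_coefficients(model, 0.0, seed=2)
        np.testing.assert_array_equal(eff.coefficients, model.coefficients)

    def test_negative_level_rejected(self):
        model = ts.draw_generative_model(20, 1)
        with pytest.raises(ValueError):
            ts.perturb_coefficients(model, -0.1, seed=2)

    def test_uniform_support_and_moments(self):
        """Perturbed coefficients are Uniform(c-l, c+l): exact support, matching moments."""
        model = ts.draw_generative_model(20, 5)
        c = model.coefficients
        l = 1.0
        rng = np.random.default_rng(8)
        draws = np.array(
            [ts.perturb_coefficients(model, l, rng).coefficients for _ in range(10_000)]
        )
        assert np.all(draws >= c - l) and np.all(draws <= c + l)
        # moments of Uniform(c-1, c+1): mean c, variance 1/3
        np.testing.assert_allclose(draws.mean(axis=0), c, atol=0.03)
        np.testing.assert_allclose(draws.var(axis=0), 1.0 / 3.0, rtol=0.10)

    @given(l=st.floats(min_value=0.0, max_value=10.0), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_support_property(self, l, seed):
        model = ts.draw_generative_model(15, 3)
        eff = ts.perturb_coefficients(model, l, seed=seed)
        assert np.all(eff.coefficients >= model.coefficients - l - 1e-12)
        assert np.all(eff.coefficients <= model.coefficients + l + 1e-12)


class TestOutcome:
    def test_noiseless_single_variable_is_exact_linear(self, rng):
        model = ts.draw_generative_model(10, 2, noise_sd=0.0)
        eff = model.base_effects()
        X = rng.normal(size=(50, 10))
        y = ts.generate_outcome(X, eff, seed=0)
        np.testing.assert_allclose(y, X[:, model.true_idx] @ model.coefficients)

    def test_binary_outcome_is_bernoulli(self, rng):
        model = ts.draw_generative_model(10, 2, outcome_type="binary")
        X = rng.normal(size=(200, 10))
        y = ts.generate_outcome(X, model.base_effects(), seed=1)
        assert set(np.unique(y)).issubset({0.0, 1.0})

    def test_interaction_share_zero_without_interactions(self, rng):
        model = ts.draw_generative_model(10, 2)
        X = rng.normal(size=(100, 10))
        assert ts.interaction_variance_share(X, model.base_effects()) == 0.0

    def test_interaction_share_monotone_in_strength(self):
        """Share of outcome variance from interactions grows with their coefficients."""
        shares = []
        for s in (0.0, 1.0, 2.0, 3.0):
            rng = np.random.default_rng(33)
            vals = []
            for _ in range(50):
                model = ts.draw_generative_model(
                    30, rng, interaction_scenario="two_train_two_test",
                    interaction_strength=s,
                )
                X = ts.sample_features(ts.MVNSpec(), 200, 30, rng)
                vals.append(ts.interaction_variance_share(X, model.base_effects()))
            shares.append(np.mean(vals))
        assert shares[0] == 0.0
        assert all(b > a for a, b in zip(shares, shares[1:]))


class TestBuildCollection:
    def test_multi_study_counts_and_levels(self, small_config):
        collection, model = ts.build_collection(small_config, 7)
        assert collection.K == 4 and collection.V == 2
        levels = sorted(
            model.study_effects[s.study_id].heterogeneity
            for s in collection.train_studies
        )
        assert levels == [0.25, 0.25, 1.0, 1.0]
        for s in collection.validate_studies:
            assert model.study_effects[s.study_id].heterogeneity == 0.5

    @pytest.mark.parametrize("scenario,expected", [
        ("two_train_two_test", (2, 2)),
        ("none", (0, 0)),
    ])
    def test_interaction_placement(self, scenario, expected):
        cfg = ts.ScenarioConfig(
            K=6, V=3, n_per_study=20, p=12, m=2, mtry=4,
            heterogeneity=ts.HeterogeneityProfile(interaction_scenario=scenario),
        )
        collection, model = ts.build_collection(cfg, 9)
        n_train = sum(
            model.study_effects[s.study_id].has_interactions
            for s in collection.train_studies
        )
        n_val = sum(
            model.study_effects[s.study_id].has_interactions
            for s in collection.validate_studies
        )
        assert (n_train, n_val) == expected
        assert INTERACTION_PLACEMENT[scenario] == expected

    def test_repeated_single_study_shares_features(self):
        cfg = ts.ScenarioConfig(
            mode="repeated_single_study", K=3, V=2, n_per_study=25, p=12, m=2, mtry=4,
        )
        collection, _ = ts.build_collection(cfg, 11)
        train = collection.train_studies
        for s in train[1:]:
            np.testing.assert_array_equal(s.features, train[0].features)
        # validation studies are independent draws
        assert not np.array_equal(
            collection.validate_studies[0].features[: 25], train[0].features
        )

    def test_zero_heterogeneity_shares_coefficients(self):
        cfg = ts.ScenarioConfig(
            K=3, V=1, n_per_study=20, p=12, m=2, mtry=4,
            heterogeneity=ts.HeterogeneityProfile(l_low=0.0, l_high=0.0, l_validate=0.0),
        )
        collection, model = ts.build_collection(cfg, 13)
        coefs = [model.study_effects[s.study_id].coefficients for s in collection.studies]
        for c in coefs[1:]:
            np.testing.assert_array_equal(c, coefs[0])

    def test_pseudo_split_partitions_source(self, rng):
        src = rng.normal(size=(53, 12))
        cfg = ts.ScenarioConfig(
            mode="pseudo_split", K=4, V=1, n_per_study=10, p=12,
            feature_source=ts.ResampleSpec(matrix=src), m=2, mtry=4,
        )
        collection, _ = ts.build_collection(cfg, 17)
        assert collection.K == 4 and collection.V == 1
        sizes = [s.n for s in collection.studies]
        assert sizes == [10, 10, 10, 10, 13]  # remainder goes to the last part
        rows = np.vstack([s.features for s in collection.studies])
        assert rows.shape[0] == 53
        # disjoint: every source row appears exactly once
        assert np.array_equal(
            np.sort(rows, axis=0), np.sort(src, axis=0)
        )

    def test_roundtrip_io(self, tmp_path, small_collection):
        collection, _ = small_collection
        ts.write_collection(collection, tmp_path, seed=12345)
        back = ts.read_collection(tmp_path)
        assert [s.study_id for s in back.studies] == [s.study_id for s in collection.studies]
        for a, b in zip(back.studies, collection.studies):
            np.testing.assert_allclose(a.features, b.features)
            np.testing.assert_allclose(a.outcome, b.outcome)
            assert a.role == b.role


def test_config_yaml_roundtrip(tmp_path, small_config):
    path = tmp_path / "cfg.yaml"
    small_config.to_yaml(path)
    back = ts.ScenarioConfig.from_yaml(path)
    assert back == small_config
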