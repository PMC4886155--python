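"""Model core: covariance builders, likelihoods, twin-wise deletion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

import twinfiml as tf
from twinfiml.model import covariate_covariance, joint_covariance, joint_mean
from conftest import random_valid_model


class TestACECovariance:
    @pytest.mark.parametrize(
        "zyg,expected_off", [(tf.Zygosity.MZ, 0.8), (tf.Zygosity.DZ, 0.55)]
    )
    def test_design_values(self, ace, zyg, expected_off):
        got = tf.ace_covariance(ace, zyg)
        np.testing.assert_allclose(
            got, [[1.0, expected_off], [expected_off, 1.0]], atol=1e-15
        )

    def test_pure_unique_environment_gives_identity(self):
        ace = tf.ACEParams(0.0, 0.0, 1.0)
        for zyg in tf.Zygosity:
            np.testing.assert_array_equal(tf.ace_covariance(ace, zyg), np.eye(2))

    def test_invalid_zygosity_rejected(self, ace):
        with pytest.raises(TypeError):
            tf.ace_covariance(ace, "MZ-ish")


class TestCovariateCovariance:
    def test_matches_entrywise_assembly(self):
        rng = np.random.default_rng(3)
        model = random_valid_model(rng, K=2)
        cov = model.cov
        got = covariate_covariance(cov)
        expected = np.empty((4, 4))
        for i in range(2):
            for j in range(2):
                for a in range(2):
                    for b in range(2):
                        within = cov.Sigma_w[i, j] if a == b else 0.0
                        expected[a * 2 + i, b * 2 + j] = within + cov.Sigma_b[i, j]
        np.testing.assert_allclose(got, expected, atol=1e-14)

    def test_zero_between_pair_gives_identity(self):
        cov = tf.CovariateStructure(1, [0.0], [[1.0]], [[0.0]])
        np.testing.assert_array_equal(covariate_covariance(cov), np.eye(2))


class TestJointModel:
    def test_zero_weights_block_diagonal(self, ace, cov5):
        model = tf.JointModel(ace, cov5, tf.RegressionWeights(np.zeros(5)))
        sigma = joint_covariance(model, tf.Zygosity.DZ)
        np.testing.assert_allclose(sigma[:2, :2], tf.ace_covariance(ace, tf.Zygosity.DZ))
        np.testing.assert_allclose(sigma[2:, 2:], covariate_covariance(cov5))
        np.testing.assert_allclose(sigma[:2, 2:], 0.0, atol=1e-15)

    def test_joint_mean_conventions(self):
        cov = tf.CovariateStructure(1, [2.0], [[1.0]], [[0.5]])
        ace = tf.ACEParams(0.5, 0.3, 0.2, mu_y=0.0)
        model = tf.JointModel(ace, cov, tf.RegressionWeights([0.5]))
        np.testing.assert_allclose(joint_mean(model), [1.0, 1.0, 2.0, 2.0])
        model0 = tf.JointModel(
            tf.ACEParams(0.5, 0.3, 0.2, mu_y=1.0), cov, tf.RegressionWeights([0.0])
        )
        np.testing.assert_allclose(joint_mean(model0), [1.0, 1.0, 2.0, 2.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), K=st.integers(1, 3))
    def test_schur_reduction_recovers_conditional_model(self, seed, K):
        """Conditioning the joint normal on the covariates must reproduce the
        ACE residual covariance and the linear conditional-mean slope."""
        model = random_valid_model(np.random.default_rng(seed), K)
        beta = model.weights.beta
        for zyg in tf.Zygosity:
            sigma = joint_covariance(model, zyg)
            syy, syx, sxx = sigma[:2, :2], sigma[:2, 2:], sigma[2:, 2:]
            cond_cov = syy - syx @ np.linalg.solve(sxx, syx.T)
            np.testing.assert_allclose(cond_cov, tf.ace_covariance(model.ace, zyg), atol=1e-10)
            slope = syx @ np.linalg.inv(sxx)
            expected = np.zeros((2, 2 * K))
            expected[0, :K] = beta
            expected[1, K:] = beta
            np.testing.assert_allclose(slope, expected, atol=1e-9)

    def test_dimension_mismatch_rejected(self, ace, cov5):
        with pytest.raises(ValueError):
            tf.JointModel(ace, cov5, tf.RegressionWeights(np.zeros(3)))

    def test_zygosity_specific_covariate_structure(self, ace):
        shared = tf.CovariateStructure.exchangeable(2)
        dz_only = tf.CovariateStructure.exchangeable(2, b_corr=0.2)
        model = tf.JointModel(ace, shared, tf.RegressionWeights([0.1, 0.1]), cov_dz=dz_only)
        mz = joint_covariance(model, tf.Zygosity.MZ)
        dz = joint_covariance(model, tf.Zygosity.DZ)
        np.testing.assert_allclose(mz[2:, 2:], covariate_covariance(shared))
        np.testing.assert_allclose(dz[2:, 2:], covariate_covariance(dz_only))
        with pytest.raises(ValueError, match="mu_x"):
            tf.JointModel(
                ace, shared, tf.RegressionWeights([0.1, 0.1]),
                cov_dz=tf.CovariateStructure.exchangeable(2, mu_x=[1.0, 0.0]),
            )


class TestObservedSubmodel:
    def test_full_mask_is_identity(self, design_model):
        mu = joint_mean(design_model)
        sigma = joint_covariance(design_model, tf.Zygosity.MZ)
        m, s = tf.observed_submodel(mu, sigma, np.ones(mu.size, bool))
        np.testing.assert_array_equal(m, mu)
        np.testing.assert_array_equal(s, sigma)

    def test_single_coordinate(self, design_model):
        mu = joint_mean(design_model)
        sigma = joint_covariance(design_model, tf.Zygosity.DZ)
        mask = np.zeros(mu.size, bool)
        mask[3] = True
        m, s = tf.observed_submodel(mu, sigma, mask)
        assert m[0] == mu[3] and s[0, 0] == sigma[3, 3]

    def test_empty_mask_rejected(self, design_model):
        mu = joint_mean(design_model)
        sigma = joint_covariance(design_model, tf.Zygosity.DZ)
        with pytest.raises(ValueError):
            tf.observed_submodel(mu, sigma, np.zeros(mu.size, bool))


class TestFullInformationLoglik:
    def test_permutation_invariance(self, small_mar_dataset, design_model):
        model = random_valid_model(np.random.default_rng(0), 2)
        data = small_mar_dataset
        perm = np.random.default_rng(1).permutation(len(data))
        assert tf.loglik_full_information(data, model) == pytest.approx(
            tf.loglik_full_information(data.subset(perm), model), abs=1e-8
        )

    def test_duplicating_records_doubles_loglik(self, small_mar_dataset):
        model = random_valid_model(np.random.default_rng(2), 2)
        data = small_mar_dataset.subset(np.arange(40))
        doubled = tf.TwinDataset.from_records(list(data.records()) * 2)
        assert tf.loglik_full_information(doubled, model) == pytest.approx(
            2.0 * tf.loglik_full_information(data, model), rel=1e-12
        )

    def test_agrees_with_pattern_sufficient_statistics(self, small_mar_dataset):
        from twinfiml._likelihood import PatternStats, loglik_patterns

        model = random_valid_model(np.random.default_rng(5), 2)
        mu = joint_mean(model)
        sig = {
            1: joint_covariance(model, tf.Zygosity.MZ),
            0: joint_covariance(model, tf.Zygosity.DZ),
        }
        fast = loglik_patterns(mu, sig, PatternStats(small_mar_dataset))
        ref = tf.loglik_full_information(small_mar_dataset, model)
        assert fast == pytest.approx(ref, rel=1e-10)

    def test_complete_data_factorizes(self, small_complete_dataset):
        """With no missing data the joint likelihood splits into the
        conditional phenotype likelihood times the covariate marginal."""
        model = random_valid_model(np.random.default_rng(4), 2)
        data = small_complete_dataset
        ll_joint = tf.loglik_full_information(data, model)
        ll_cond = tf.loglik_usual(data, model.ace, model.weights)
        x_stacked = np.concatenate([data.X[:, 0, :], data.X[:, 1, :]], axis=1)
        ll_marg = multivariate_normal(
            np.concatenate([model.cov.mu_x] * 2), covariate_covariance(model.cov)
        ).logpdf(x_stacked).sum()
        assert ll_joint == pytest.approx(ll_cond + ll_marg, abs=1e-8)


class TestTwinwiseDelete:
    def _toy(self):
        y = np.array([[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]])
        X = np.ones((3, 2, 2))
        X[1, 0, 1] = np.nan  # pair 2: twin 1 incomplete
        X[2, 0, 0] = np.nan  # pair 3: both twins incomplete
        X[2, 1, 1] = np.nan
        return tf.TwinDataset(["a", "b", "c"], ["MZ", "DZ", "DZ"], y, X)

    def test_enumeration_of_retained_individuals(self):
        out = tf.twinwise_delete(self._toy())
        assert len(out) == 2  # fully-incomplete pair dropped
        retained = out.y_observed.sum()
        assert retained == 3  # 2 (complete pair) + 1 (singleton co-twin)
        # the singleton's removed side lost phenotype AND covariates
        assert np.isnan(out.y[1, 0]) and np.isnan(out.X[1, 0]).all()
        assert not np.isnan(out.y[1, 1]) and not np.isnan(out.X[1, 1]).any()

    def test_complete_data_unchanged(self, small_complete_dataset):
        out = tf.twinwise_delete(small_complete_dataset)
        np.testing.assert_array_equal(out.y, small_complete_dataset.y)
        np.testing.assert_array_equal(out.X, small_complete_dataset.X)


class TestUsualLoglik:
    def test_singleton_closed_form(self):
        y = np.array([[0.0, np.nan]])
        X = np.zeros((1, 2, 1))
        X[0, 1, 0] = np.nan
        data = tf.TwinDataset(["f"], ["MZ"], y, X)
        ll = tf.loglik_usual(data, tf.ACEParams(0.5, 0.3, 0.2), tf.RegressionWeights([1.0]))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_precondition_violation_detected(self, small_mar_dataset):
        with pytest.raises(ValueError, match="twin-wise deleted"):
            tf.loglik_usual(
                small_mar_dataset, tf.ACEParams(0.5, 0.3, 0.2), tf.RegressionWeights([0.0, 0.0])
            )

    def test_empty_collection_contributes_zero(self):
        assert tf.loglik_usual(None, tf.ACEParams(0.5, 0.3, 0.2), tf.RegressionWeights([0.0])) == 0.0


class TestHeritability:
    @pytest.mark.parametrize(
        "a,c,e,expected", [(0.5, 0.3, 0.2, 0.5), (0.0, 0.7, 0.3, 0.0), (2.0, 0.0, 1e-9, 1.0)]
    )
    def test_values(self, a, c, e, expected):
        assert tf.heritability(tf.ACEParams(a, c, e)) == pytest.approx(expected, abs=1e-6)


class TestValidation:
    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            tf.ACEParams(-0.1, 0.3, 0.2)
        with pytest.raises(ValueError):
            tf.ACEParams(0.5, 0.3, 0.0)

    def test_asymmetric_structure_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            tf.CovariateStructure(2, [0, 0], [[1.0, 0.5], [0.1, 1.0]], np.eye(2))

    def test_zero_information_pair_rejected(self):
        with pytest.raises(ValueError, match="no observed entry"):
            tf.TwinDataset(
                ["f"], ["MZ"], np.full((1, 2), np.nan), np.full((1, 2, 2), np.nan)
            )
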