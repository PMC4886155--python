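"""Estimators: equivalences, invariances, standard errors."""

import numpy as np
import pytest

import twinfiml as tf
from twinfiml.fit import _FullParamMap
from twinfiml._likelihood import PatternStats, loglik_patterns


class TestCompleteDataEquivalence:
    def test_full_information_matches_usual_on_complete_data(self, small_complete_dataset):
        full = tf.fit_full_information(small_complete_dataset, compute_se=False)
        usual = tf.fit_usual(small_complete_dataset, compute_se=False)
        assert full.converged and usual.converged
        for attr in ("sigma2_A", "sigma2_C", "sigma2_E", "mu_y"):
            assert getattr(full.ace, attr) == pytest.approx(getattr(usual.ace, attr), abs=1e-4)
        np.testing.assert_allclose(full.weights.beta, usual.weights.beta, atol=1e-4)


class TestFitInvariances:
    def test_twin_order_swap_leaves_likelihood_unchanged(self, small_mar_dataset):
        data = small_mar_dataset
        swapped = tf.TwinDataset(
            data.family_id, data.zygosity, data.y[:, ::-1], data.X[:, ::-1, :]
        )
        a = tf.fit_full_information(data, compute_se=False)
        b = tf.fit_full_information(swapped, compute_se=False)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-5)

    def test_likelihood_at_maximizer_beats_truth(self, small_mar_dataset, design_model):
        truth2 = tf.JointModel(
            tf.ACEParams(0.5, 0.3, 0.2),
            tf.CovariateStructure.exchangeable(2),
            tf.solve_equal_beta(0.39, tf.ACEParams(0.5, 0.3, 0.2), tf.CovariateStructure.exchangeable(2)),
        )
        fitted = tf.fit_full_information(small_mar_dataset, compute_se=False)
        ll_truth = tf.loglik_full_information(small_mar_dataset, truth2)
        assert fitted.loglik >= ll_truth - 1e-6

    def test_reparameterization_invariance(self, small_mar_dataset):
        """Optimizing on the unconstrained scale must reach the same maximum
        as a box-constrained optimizer in the natural parameterization."""
        from scipy.optimize import minimize

        data = small_mar_dataset
        pmap = _FullParamMap(data.K)
        stats = PatternStats(data)
        fitted = tf.fit_full_information(data, compute_se=False)

        def nll_natural(phi):
            mu, sig = pmap.build_natural(phi)
            ll = loglik_patterns(mu, sig, stats)
            return -ll if np.isfinite(ll) else 1e12

        phi0 = pmap.natural_from_estimates(
            np.array([0.4, 0.3, 0.3]) * np.var(data.y[~np.isnan(data.y)]),
            0.0,
            np.zeros(data.K),
            np.zeros(data.K),
            np.eye(data.K),
            0.5 * np.eye(data.K),
        )
        bounds = [(1e-6, None)] * 3 + [(None, None)] * (phi0.size - 3)
        res = minimize(
            nll_natural, phi0, method="L-BFGS-B", bounds=bounds,
            options=dict(maxiter=4000, ftol=1e-12),
        )
        assert fitted.loglik == pytest.approx(-res.fun, abs=1e-5)

    def test_usual_fit_counts_match_deletion(self, small_mar_dataset):
        res = tf.fit_usual(small_mar_dataset, compute_se=False)
        deleted = tf.twinwise_delete(small_mar_dataset)
        complete = deleted.y_observed
        assert res.n_pairs_used == int(complete.all(axis=1).sum())
        assert res.n_singletons_used == int(complete.sum() - 2 * res.n_pairs_used)

    def test_empty_after_deletion_raises(self):
        y = np.array([[0.0, 1.0]])
        X = np.full((1, 2, 1), np.nan)
        data = tf.TwinDataset(["f"], ["DZ"], y, X)
        with pytest.raises(ValueError):
            tf.fit_usual(data)


class TestStandardErrors:
    def test_quadratic_loglik_recovers_exact_ses(self):
        h = np.array([[4.0, 1.0], [1.0, 2.0]])

        def loglik(x):
            return -0.5 * x @ h @ x

        se = tf.standard_errors(loglik, np.zeros(2))
        np.testing.assert_allclose(se, np.sqrt(np.diag(np.linalg.inv(h))), rtol=1e-5)

    def test_se_shrinks_like_root_n(self):
        ses = {}
        for n in (500, 2000, 8000):
            config = tf.SimulationConfig(
                n_mz=int(0.28 * n), n_dz=int(0.72 * n),
                cov=tf.CovariateStructure.exchangeable(2),
            )
            data = tf.simulate_dataset(config, 50 + n)
            ses[n] = tf.fit_usual(data).se["sigma2_A"]
        assert ses[500] / ses[2000] == pytest.approx(2.0, rel=0.25)
        assert ses[2000] / ses[8000] == pytest.approx(2.0, rel=0.25)

    def test_h2_delta_se_close_to_bootstrap(self):
        config = tf.SimulationConfig(
            n_mz=120, n_dz=280, cov=tf.CovariateStructure.exchangeable(1)
        )
        data = tf.simulate_dataset(config, 60)
        fit = tf.fit_usual(data)
        rng = np.random.default_rng(61)
        h2s = []
        for _ in range(100):
            idx = rng.integers(0, len(data), size=len(data))
            h2s.append(tf.fit_usual(data.subset(idx), compute_se=False).h2)
        boot_se = np.std(h2s, ddof=1)
        assert fit.h2_se == pytest.approx(boot_se, rel=0.20)

    def test_full_information_ses_present_and_positive(self, small_mar_dataset):
        res = tf.fit_full_information(small_mar_dataset)
        for name in ("sigma2_A", "sigma2_C", "sigma2_E", "beta_1"):
            assert np.isfinite(res.se[name]) and res.se[name] > 0
        assert np.isfinite(res.h2_se) and res.h2_se > 0


class TestBiasDirections:
    def test_usual_underestimates_shared_environment_under_mar(self):
        """Phenotype-dependent deletion removes low scorers, shrinking the
        apparent between-family variance for the deletion estimator."""
        biases = []
        for rep in range(8):
            data = tf.simulate_dataset(tf.SimulationConfig(), 70 + rep)
            data = tf.impose_missingness(data, tf.MissingnessSpec("MAR", 0.10), 170 + rep)
            biases.append(tf.fit_usual(data, compute_se=False).ace.sigma2_C - 0.3)
        assert np.mean(biases) < -0.05


class TestExchangeableStructureOption:
    def test_exchangeable_fit_matches_free_fit_on_design_data(self):
        """The generating structure is exchangeable, so the constrained fit
        should reach nearly the free fit's component estimates."""
        config = tf.SimulationConfig(n_mz=280, n_dz=720, cov=tf.CovariateStructure.exchangeable(3))
        data = tf.simulate_dataset(config, 80)
        data = tf.impose_missingness(data, tf.MissingnessSpec("MCAR", 0.06), 81)
        free = tf.fit_full_information(data, compute_se=False)
        ex = tf.fit_full_information(data, compute_se=False, covariate_structure="exchangeable")
        assert ex.converged
        assert free.loglik >= ex.loglik - 1e-6  # nested models
        assert ex.ace.sigma2_A == pytest.approx(free.ace.sigma2_A, abs=0.02)
        assert ex.ace.sigma2_C == pytest.approx(free.ace.sigma2_C, abs=0.02)
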