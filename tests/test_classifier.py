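"""Gaussian covariance classifier, chance threshold and similarity ratio."""

import numpy as np
import pytest
from scipy.special import comb

from hopfnet import (
    RoiTimeSeries,
    chance_threshold,
    fit_gaussian,
    jackknife_classify,
    log_likelihood,
    similarity_ratio,
)
from hopfnet.exceptions import DesignError, ShapeError


def _ts(data, subject="s0", state="a"):
    return RoiTimeSeries(data=data, tr=2.0, subject=subject, state=state)


def _mvn_cohort(n_subjects, n_rois, t, rho_a, rho_b, seed):
    """Paired cohort drawn from two zero-mean Gaussians with uniform
    off-diagonal correlation rho per state."""
    rng = np.random.default_rng(seed)
    cohort = []
    for state, rho in (("a", rho_a), ("b", rho_b)):
        cov = np.full((n_rois, n_rois), rho)
        np.fill_diagonal(cov, 1.0)
        chol = np.linalg.cholesky(cov)
        for s in range(n_subjects):
            data = chol @ rng.normal(size=(n_rois, t))
            data = (data - data.mean(1, keepdims=True)) / data.std(1, keepdims=True)
            cohort.append(_ts(data, subject=f"s{s}", state=state))
    return cohort


class TestFitGaussian:
    def test_iid_noise_recovers_identity(self, rng):
        ts = _ts(rng.normal(size=(10, 10_000)))
        model = fit_gaussian([ts])
        assert np.linalg.norm(model.sigma - np.eye(10)) < 0.2

    def test_duplicated_series_leave_covariance_unchanged(self, rng):
        ts = _ts(rng.normal(size=(4, 500)))
        single = fit_gaussian([ts]).sigma
        double = fit_gaussian([ts, ts]).sigma
        assert np.allclose(single, double)

    def test_perfectly_correlated_pair(self, rng):
        row = rng.normal(size=2000)
        row = (row - row.mean()) / row.std()
        ts = _ts(np.vstack([row, row, rng.normal(size=2000)]))
        model = fit_gaussian([ts])
        assert model.sigma[0, 1] == pytest.approx(1.0, abs=1e-6)
        assert model.ridge > 0  # duplicated rows make sigma singular

    def test_empty_train_set(self):
        with pytest.raises(DesignError):
            fit_gaussian([])


class TestLogLikelihood:
    def test_standard_normal_at_mode(self):
        import scipy.linalg as la

        from hopfnet.classifier import GaussianModel

        sigma = np.eye(2)
        ident = GaussianModel(
            sigma=sigma, cho=la.cho_factor(sigma, lower=True), log_det=0.0
        )
        x = np.zeros((2, 1))
        assert log_likelihood(x, ident) == pytest.approx(-np.log(2 * np.pi))

    def test_scaling_covariance_costs_half_T_N_log_c(self):
        from hopfnet.classifier import _fit_cov

        n, t, c = 3, 7, 2.5
        x = np.zeros((n, t))
        base = _fit_cov(np.random.default_rng(2).normal(size=(n, 200)))
        scaled = _fit_cov(np.sqrt(c) * np.random.default_rng(2).normal(size=(n, 200)))
        # exact closed form: L(x=0) depends only on log det
        expected_drop = 0.5 * t * n * np.log(c)
        assert log_likelihood(x, base) - log_likelihood(x, scaled) == pytest.approx(
            expected_drop, rel=1e-10
        )

    def test_invariant_under_simultaneous_permutation(self, rng):
        data = rng.normal(size=(5, 100))
        model = fit_gaussian([_ts(rng.normal(size=(5, 3000)))])
        perm = rng.permutation(5)
        from hopfnet.classifier import GaussianModel, _fit_cov
        import scipy.linalg as la

        sigma_p = model.sigma[np.ix_(perm, perm)]
        model_p = GaussianModel(
            sigma=sigma_p, cho=la.cho_factor(sigma_p, lower=True),
            log_det=model.log_det,
        )
        assert log_likelihood(data[perm], model_p) == pytest.approx(
            log_likelihood(data, model), rel=1e-9
        )

    def test_dimension_mismatch(self, rng):
        model = fit_gaussian([_ts(rng.normal(size=(4, 500)))])
        with pytest.raises(ShapeError):
            log_likelihood(rng.normal(size=(5, 10)), model)

    def test_finite_for_spd_models(self, rng):
        model = fit_gaussian([_ts(rng.normal(size=(6, 400)))])
        values = [log_likelihood(rng.normal(size=(6, 50)), model) for _ in range(20)]
        assert np.all(np.isfinite(values))


class TestJackknife:
    def test_separable_states_classified_accurately(self):
        cohort = _mvn_cohort(8, 10, 300, rho_a=0.6, rho_b=0.0, seed=0)
        report = jackknife_classify(cohort)
        assert report.per_state_accuracy["a"] >= 0.9
        assert report.per_state_accuracy["b"] >= 0.9
        assert len(report.records) == 16

    def test_identical_states_near_chance(self):
        cohort = _mvn_cohort(12, 6, 120, rho_a=0.3, rho_b=0.3, seed=1)
        report = jackknife_classify(cohort)
        for acc in report.per_state_accuracy.values():
            assert 0.1 <= acc <= 0.9  # chance 0.5 +- binomial noise, n=12

    def test_requires_three_subjects(self):
        cohort = _mvn_cohort(2, 4, 60, 0.5, 0.0, seed=2)
        with pytest.raises(DesignError):
            jackknife_classify(cohort)


class TestChanceThreshold:
    def test_matches_exhaustive_binomial_tail(self):
        n, alpha = 18, 0.05
        # independent oracle: exhaustive sum of the binomial pmf
        def tail(k):
            return sum(comb(n, j) * 0.5**n for j in range(k, n + 1))

        expected = next(k for k in range(n + 1) if tail(k) < alpha)
        assert chance_threshold(n, alpha) == expected

    def test_unattainable_for_tiny_n(self):
        assert chance_threshold(1, 0.05) is None

    def test_monotone_in_alpha(self):
        thresholds = [chance_threshold(18, a) for a in (0.01, 0.05, 0.2)]
        assert thresholds[0] >= thresholds[1] >= thresholds[2]


class TestSimilarityRatio:
    def test_same_generator_subject_ratio_near_one(self):
        cohort = _mvn_cohort(6, 5, 150, rho_a=0.4, rho_b=0.4, seed=3)
        entry = similarity_ratio(cohort, "s0", "a", n_resamples=50, seed=0)
        assert 0.67 <= entry.mean_ratio <= 1.52

    def test_mean_stable_across_seeds(self):
        cohort = _mvn_cohort(6, 5, 150, rho_a=0.4, rho_b=0.4, seed=3)
        means = [
            similarity_ratio(cohort, "s1", "a", n_resamples=50, seed=s).mean_ratio
            for s in range(4)
        ]
        assert np.std(means) < 0.1

    def test_insufficient_pool_rejected(self):
        cohort = _mvn_cohort(2, 5, 150, 0.4, 0.4, seed=4)
        with pytest.raises(DesignError):
            similarity_ratio(cohort, "s0", "a", n_resamples=5, seed=0)
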