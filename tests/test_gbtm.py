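"""Zero-inflated Poisson trajectory mixture: likelihood oracles, EM
behaviour and parameter recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson
from sklearn.metrics import adjusted_rand_score

from costtraj import (ZipTrajectoryModel, information_criteria,
                      patient_loglik, posterior_assign, simulate_cohort,
                      time_basis, zip_logpmf)
from costtraj.gbtm import _CLIP


class TestZipLogPmf:
    def test_zero_inflation_off_reduces_to_poisson(self):
        assert zip_logpmf(0, 2.0, 0.0) == pytest.approx(-2.0, abs=1e-12)

    def test_degenerate_zero_mass(self):
        assert zip_logpmf(0, 5.0, 1 - 1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_positive_count_closed_form(self):
        expected = np.log(0.7) + poisson.logpmf(3, 2.0)
        assert zip_logpmf(3, 2.0, 0.3) == pytest.approx(expected, abs=1e-12)

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValueError):
            zip_logpmf(-1, 1.0, 0.1)
        with pytest.raises(ValueError):
            zip_logpmf(1.5, 1.0, 0.1)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(y=st.integers(0, 50), lam=st.floats(0.01, 100.0),
           p=st.floats(0.0, 0.99))
    def test_matches_direct_mixture_formula(self, y, lam, p):
        if y == 0:
            direct = np.log(p + (1 - p) * np.exp(-lam))
        else:
            direct = np.log1p(-p) + poisson.logpmf(y, lam)
        assert zip_logpmf(y, lam, p) == pytest.approx(direct, abs=1e-12)

    def test_normalization(self):
        y = np.arange(200)
        lp = zip_logpmf(y, 7.3, 0.25)
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-10)


class TestPatientLoglik:
    def test_single_observed_month_equals_single_pmf(self):
        beta = np.array([1.0, 0.5])
        gamma = np.array([-1.0])
        y = np.zeros(12, dtype=int)
        y[0] = 4
        obs = np.zeros(12, dtype=bool)
        obs[0] = True
        T = time_basis(1)
        lam = np.exp(T[0] @ beta)
        from scipy.special import expit
        p = expit(-1.0)
        expected = zip_logpmf(4, lam, p)
        got = patient_loglik(y, obs, beta, gamma, zero_inflation="constant")
        assert got == pytest.approx(float(expected), abs=1e-12)

    def test_brute_force_product_over_months(self):
        # likelihood factorises over observed months within a group
        rng = np.random.default_rng(5)
        beta = np.array([1.2, -0.4, 0.3])
        gamma = np.array([-1.5, 0.8, -0.2])
        T = time_basis(2)
        lam = np.exp(T @ beta)
        p = 1.0 / (1.0 + np.exp(-(T @ gamma)))
        for _ in range(10):
            y = rng.poisson(3.0, size=12)
            obs = rng.random(12) < 0.8
            if not obs.any():
                obs[0] = True
            prob = 1.0
            for m in range(12):
                if obs[m]:
                    if y[m] == 0:
                        prob *= p[m] + (1 - p[m]) * np.exp(-lam[m])
                    else:
                        prob *= (1 - p[m]) * poisson.pmf(y[m], lam[m])
            got = patient_loglik(y, obs, beta, gamma)
            assert got == pytest.approx(np.log(prob), rel=1e-10)

    def test_all_masked_row_rejected(self):
        with pytest.raises(ValueError, match="no observed months"):
            patient_loglik(np.zeros(12, int), np.zeros(12, bool),
                           np.array([1.0]), np.array([0.0]))


class TestEmFit:
    def test_one_group_posterior_is_ones(self, cohort3):
        _, matrix, _ = cohort3
        model = ZipTrajectoryModel(n_groups=1, degree=2,
                                   zero_inflation="constant",
                                   random_state=0).fit(matrix)
        assert model.weights_ == pytest.approx([1.0])
        assert np.allclose(model.posterior_, 1.0)

    def test_poisson_closed_form_at_degree_zero(self):
        # with no zero inflation and a flat trend the one-group rate is the
        # sample mean of the observed counts
        rng = np.random.default_rng(2)
        Y = rng.poisson(6.0, size=(40, 12))
        obs = np.ones_like(Y, dtype=bool)
        obs[:5, 6:] = False
        Y[~obs] = 0
        model = ZipTrajectoryModel(n_groups=1, degree=0, zero_inflation="none",
                                   random_state=0).fit(Y, obs)
        assert model.rates_[0, 0] == pytest.approx(Y[obs].mean(), rel=1e-8)

    def test_two_group_parameter_recovery(self):
        from costtraj import SimConfig
        cfg = SimConfig(
            n_patients=300, pi=[0.55, 0.45],
            beta=np.array([[3.2, 0.8, -0.8], [0.8, 0.5, 0.0]]),
            gamma=np.log(0.2 / 0.8) * np.ones((2, 1)),
            zero_inflation="constant", group_covariates=False, seed=21)
        _, matrix, labels = simulate_cohort(cfg)
        model = ZipTrajectoryModel(n_groups=2, degree=2,
                                   zero_inflation="constant",
                                   random_state=0).fit(matrix)
        assert adjusted_rand_score(labels, model.labels_) > 0.9
        truth = np.sort(cfg.pi)[::-1]
        assert np.abs(np.sort(model.weights_)[::-1] - truth).max() < 0.05

    def test_loglik_trace_monotone(self, cohort3):
        _, matrix, _ = cohort3
        model = ZipTrajectoryModel(n_groups=3, degree=2,
                                   zero_inflation="constant",
                                   random_state=1).fit(matrix)
        assert np.diff(model.loglik_trace_).min() >= -1e-8

    def test_posterior_rows_and_mixing_fixed_point(self, cohort3):
        _, matrix, _ = cohort3
        model = ZipTrajectoryModel(n_groups=3, degree=2,
                                   zero_inflation="constant",
                                   random_state=1).fit(matrix)
        assert np.abs(model.posterior_.sum(axis=1) - 1.0).max() < 1e-10
        # at convergence pi equals the mean posterior per group
        assert np.abs(model.posterior_.mean(axis=0) - model.weights_).max() < 1e-4

    def test_order_invariance_of_loglik(self, cohort3):
        _, matrix, _ = cohort3
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_patients)
        a = ZipTrajectoryModel(n_groups=3, degree=2, zero_inflation="constant",
                               random_state=5).fit(matrix)
        b = ZipTrajectoryModel(n_groups=3, degree=2, zero_inflation="constant",
                               random_state=5).fit(matrix.values[perm],
                                                   matrix.observed[perm])
        assert a.loglik_ == pytest.approx(b.loglik_, rel=1e-6)

    def test_seed_reproducibility(self, cohort3):
        _, matrix, _ = cohort3
        a = ZipTrajectoryModel(n_groups=3, degree=2, zero_inflation="constant",
                               random_state=9).fit(matrix)
        b = ZipTrajectoryModel(n_groups=3, degree=2, zero_inflation="constant",
                               random_state=9).fit(matrix)
        assert a.loglik_ == b.loglik_
        assert (a.rate_coef_ == b.rate_coef_).all()
        assert (a.posterior_ == b.posterior_).all()

    def test_groups_ordered_by_decreasing_mean_cost(self, cohort3):
        _, matrix, _ = cohort3
        model = ZipTrajectoryModel(n_groups=3, degree=2,
                                   zero_inflation="constant",
                                   random_state=1).fit(matrix)
        means = model.mean_curve_.mean(axis=1)
        assert (np.diff(means) <= 0).all()

    def test_nonconvergence_is_flagged_not_raised(self, cohort3):
        _, matrix, _ = cohort3
        with pytest.warns(RuntimeWarning):
            model = ZipTrajectoryModel(n_groups=3, degree=2,
                                       zero_inflation="constant", max_iter=2,
                                       random_state=0).fit(matrix)
        assert not model.converged_

    def test_input_validation(self, cohort3):
        _, matrix, _ = cohort3
        with pytest.raises(ValueError, match="non-negative integers"):
            ZipTrajectoryModel(n_groups=2).fit(-matrix.values)
        with pytest.raises(ValueError, match="more patients"):
            ZipTrajectoryModel(n_groups=50).fit(matrix.values[:20])
        with pytest.raises(ValueError, match="observed month"):
            bad = np.zeros((12, 12), bool)
            ZipTrajectoryModel(n_groups=2).fit(np.zeros((12, 12), int), bad)

    def test_json_round_trip(self, tmp_path, cohort3):
        _, matrix, _ = cohort3
        model = ZipTrajectoryModel(n_groups=3, degree=2,
                                   zero_inflation="constant",
                                   random_state=1).fit(matrix)
        path = tmp_path / "fit.json"
        model.to_json(path)
        back = ZipTrajectoryModel.from_json(path)
        assert back.loglik_ == pytest.approx(model.loglik_)
        assert np.allclose(back.rates_, model.rates_)
        assert np.allclose(
            back.predict_proba(matrix.values, matrix.observed), model.posterior_)


class TestCriteriaAndAssignment:
    def test_information_criteria_formulas(self):
        aic, bic = information_criteria(-100.0, 5, 50)
        assert aic == pytest.approx(210.0)
        assert bic == pytest.approx(200.0 + 5 * np.log(50))

    def test_parameter_count_constant_inflation(self, cohort3):
        _, matrix, _ = cohort3
        # J=3, d=2, constant inflation: 2 mixing + 9 rate + 3 inflation
        model = ZipTrajectoryModel(n_groups=3, degree=2,
                                   zero_inflation="constant",
                                   random_state=0).fit(matrix)
        assert model.n_parameters_ == 2 + 9 + 3
        assert model.aic_ == pytest.approx(-2 * model.loglik_ + 2 * 14)
        assert model.bic_ == pytest.approx(
            -2 * model.loglik_ + 14 * np.log(matrix.n_patients))

    def test_parameter_count_polynomial_inflation(self):
        # J=6, d=3 with per-group cubic inflation: 5 + 24 + 24
        model = ZipTrajectoryModel(n_groups=6, degree=3,
                                   zero_inflation="polynomial")
        rng = np.random.default_rng(0)
        Y = rng.poisson(4, size=(80, 12))
        model.fit(Y)
        assert model.n_parameters_ == 5 + 24 + 24

    def test_map_assignment_and_ties(self):
        labels, maxp = posterior_assign(np.array([[0.7, 0.3], [0.5, 0.5]]))
        assert list(labels) == [0, 0]  # tie breaks toward lower index
        assert list(maxp) == [0.7, 0.5]

    def test_high_max_posterior_when_separated(self, cohort3):
        _, matrix, _ = cohort3
        model = ZipTrajectoryModel(n_groups=3, degree=2,
                                   zero_inflation="constant",
                                   random_state=1).fit(matrix)
        _, maxp = posterior_assign(model.posterior_)
        assert maxp.mean() > 0.8


def test_linear_predictor_clipping_keeps_rates_positive():
    # extreme coefficients must not overflow or produce zero rates
    T = time_basis(1)
    eta = np.clip(T @ np.array([100.0, -300.0]), -_CLIP, _CLIP)
    lam = np.exp(eta)
    assert np.isfinite(lam).all() and (lam > 0).all()
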