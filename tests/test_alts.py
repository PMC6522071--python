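"""Unit and property tests for the adaptive trimmed-squares engine."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fardeep.alts import (
    ALTSParams,
    alts_fit,
    max_iterations,
    nnls_solve,
    update_overestimate,
    update_underestimate,
)

from conftest import random_nonneg_problem


def nnls_by_enumeration(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent NNLS oracle: enumerate active sets (coordinates pinned at
    zero), solve the restricted least squares, keep the feasible minimum."""
    p = X.shape[1]
    best, best_obj = None, np.inf
    for active in itertools.product([False, True], repeat=p):
        free = [j for j in range(p) if not active[j]]
        beta = np.zeros(p)
        if free:
            sol, *_ = np.linalg.lstsq(X[:, free], y, rcond=None)
            beta[free] = sol
        if np.any(beta < -1e-12):
            continue
        obj = float(np.sum((y - X @ beta) ** 2))
        if obj < best_obj - 1e-12:
            best, best_obj = np.clip(beta, 0, None), obj
    return best


class TestNNLS:
    def test_unconstrained_solution_already_nonneg(self):
        beta = nnls_solve(np.eye(2), np.array([3.0, 4.0]))
        np.testing.assert_allclose(beta, [3.0, 4.0])

    def test_constraint_active_at_zero(self):
        beta = nnls_solve(np.ones((2, 1)), np.array([-2.0, -2.0]))
        np.testing.assert_allclose(beta, [0.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_active_set_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 3, size=(6, 2))
        y = rng.normal(0, 3, size=6)
        np.testing.assert_allclose(
            nnls_solve(X, y), nnls_by_enumeration(X, y), atol=1e-8
        )

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            nnls_solve(np.array([[1.0], [np.nan]]), np.array([1.0, 2.0]))


class TestEnvelopeUpdates:
    def test_first_iteration_counts_above_median(self):
        abs_r = np.array([1.0, 2, 3, 4, 5])
        assert update_overestimate(abs_r, 3.0, k=2.0, j=1) == 2

    def test_later_iterations_use_k_and_clamp(self):
        abs_r = np.array([1.0, 2, 3, 4, 10])
        assert update_overestimate(abs_r, 3.0, k=2.0, j=2, n_over_prev=3) == 1
        # clamp enforces monotonicity even when the raw count grows
        abs_r = np.array([10.0, 10, 10, 10, 1])
        assert update_overestimate(abs_r, 1.0, k=2.0, j=3, n_over_prev=2) == 2

    def test_threshold_is_strict(self):
        abs_r = np.array([3.0, 3.0, 3.0])
        assert update_overestimate(abs_r, 3.0, k=1.0, j=1) == 0

    @pytest.mark.parametrize(
        "j,n_over,n_under_prev,alpha1,alpha2,expected",
        [
            (1, 37, None, 0.1, 1.5, 4),   # ceil(3.7)
            (2, 10, 4, 0.1, 1.5, 6),      # min(ceil(6), 10)
            (2, 5, 4, 0.1, 1.5, 5),       # clamped to the overestimate
        ],
    )
    def test_underestimate_examples(self, j, n_over, n_under_prev, alpha1, alpha2, expected):
        assert update_underestimate(n_over, n_under_prev, alpha1, alpha2, j) == expected

    def test_underestimate_rejects_bad_alphas(self):
        with pytest.raises(ValueError):
            update_underestimate(10, None, 1.2, 1.5, 1)
        with pytest.raises(ValueError):
            update_underestimate(10, None, 0.1, 0.9, 1)

    @given(
        n_over=st.integers(0, 1000),
        n_under_prev=st.integers(0, 1000),
        alpha1=st.floats(0.01, 0.99),
        alpha2=st.floats(1.01, 5.0),
    )
    def test_underestimate_never_exceeds_overestimate(self, n_over, n_under_prev, alpha1, alpha2):
        assert update_underestimate(n_over, n_under_prev, alpha1, alpha2, 2) <= n_over
        assert update_underestimate(n_over, None, alpha1, alpha2, 1) <= math.ceil(n_over)


class TestIterationBound:
    @pytest.mark.parametrize(
        "alpha1,alpha2,expected", [(0.1, 1.5, 7), (0.5, 2.0, 3)]
    )
    def test_closed_form(self, alpha1, alpha2, expected):
        assert max_iterations(alpha1, alpha2) == expected

    def test_domain_check(self):
        with pytest.raises(ValueError):
            max_iterations(0.0, 1.5)


class TestALTSFit:
    def test_noiseless_recovery_flags_nothing(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 10, size=(40, 3))
        beta = np.array([0.5, 1.2, 0.0])
        fit = alts_fit(X, X @ beta, ALTSParams(k=2.0))
        np.testing.assert_allclose(fit.beta, beta, atol=1e-8)
        assert fit.n_outliers == 0
        assert fit.converged

    def test_single_gross_outlier_detected_and_excluded(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 10, size=(50, 3))
        y = X @ np.array([1.0, 0.3, 2.0]) + rng.normal(0, 0.5, 50)
        y[17] += 1e3
        fit = alts_fit(X, y, ALTSParams(k=6.0))
        assert list(fit.outlier_index) == [17]
        clean = np.delete(np.arange(50), 17)
        oracle = nnls_solve(X[clean], y[clean])
        np.testing.assert_allclose(fit.beta, oracle, rtol=1e-10, atol=1e-12)

    def test_refit_on_retained_reproduces_beta(self, regression_instance):
        prob = regression_instance
        fit = alts_fit(prob.X, prob.y, ALTSParams(k=3.0))
        oracle = nnls_solve(prob.X[fit.retained_index], prob.y[fit.retained_index])
        np.testing.assert_allclose(fit.beta, oracle, rtol=1e-8)

    def test_partition_into_outliers_and_retained(self, regression_instance):
        prob = regression_instance
        fit = alts_fit(prob.X, prob.y, ALTSParams(k=3.0))
        merged = np.sort(np.concatenate([fit.outlier_index, fit.retained_index]))
        np.testing.assert_array_equal(merged, np.arange(len(prob.y)))

    def test_monotone_envelopes_and_meeting_point(self, regression_instance):
        prob = regression_instance
        fit = alts_fit(prob.X, prob.y, ALTSParams(k=2.0))
        overs = [s.n_over for s in fit.trace]
        unders = [s.n_under for s in fit.trace]
        assert all(a >= b for a, b in zip(overs, overs[1:]))
        assert all(a <= b for a, b in zip(unders, unders[1:]))
        assert all(u <= o for u, o in zip(unders, overs))
        assert fit.converged and overs[-1] == unders[-1]

    def test_scale_equivariance(self, regression_instance):
        prob = regression_instance
        fit1 = alts_fit(prob.X, prob.y, ALTSParams(k=3.0))
        c = 37.5
        fit2 = alts_fit(prob.X * c, prob.y * c, ALTSParams(k=3.0))
        np.testing.assert_array_equal(fit1.outlier_index, fit2.outlier_index)
        np.testing.assert_allclose(fit1.residuals * c, fit2.residuals, rtol=1e-7)

    @pytest.mark.parametrize("seed", range(25))
    def test_iteration_count_respects_bound(self, seed):
        rng = np.random.default_rng(seed)
        alpha1 = rng.uniform(0.02, 0.95)
        alpha2 = rng.uniform(1.05, 4.0)
        X, y = random_nonneg_problem(rng, n=60, p=4)
        y[rng.choice(60, 8, replace=False)] += rng.uniform(50, 200, 8)
        fit = alts_fit(X, y, ALTSParams(k=rng.uniform(1, 6), alpha1=alpha1, alpha2=alpha2))
        assert fit.n_iter <= max_iterations(alpha1, alpha2)

    def test_identifiability_cap_keeps_enough_rows(self, caplog):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 5, size=(12, 2))
        y = rng.uniform(500, 1000, size=12)  # everything looks outlying
        fit = alts_fit(X, y, ALTSParams(k=1.0))
        assert len(fit.retained_index) >= X.shape[1] + 1

    def test_ols_mode_matches_lstsq_on_clean_data(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 3))
        beta = np.array([1.0, -2.0, 0.5])  # negative coefficient needs OLS
        y = X @ beta
        fit = alts_fit(X, y, ALTSParams(k=2.0, nonneg=False))
        np.testing.assert_allclose(fit.beta, beta, atol=1e-8)

    def test_intercept_column_absorbs_constant_shift(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 10, size=(60, 2))
        beta = np.array([1.5, 0.7])
        y = X @ beta - 25.0  # negative offset: intercept must be sign-free
        fit = alts_fit(X, y, ALTSParams(k=3.0, intercept=True))
        np.testing.assert_allclose(fit.beta, beta, atol=1e-6)
        assert fit.intercept_ == pytest.approx(-25.0, abs=1e-6)

    def test_rejects_underdetermined(self):
        with pytest.raises(ValueError):
            alts_fit(np.ones((3, 3)), np.ones(3), ALTSParams())
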