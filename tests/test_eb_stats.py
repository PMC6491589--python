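"""OLS fitting, the hierarchical variance prior, moderated t and BH."""

import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

from adprquant import (
    adjust_bh,
    call_significance,
    cofactor_design,
    estimate_variance_prior,
    fit_linear_models,
    moderated_t_test,
    squeeze_variances,
)
from adprquant.design import DesignMatrix
from adprquant.eb_stats import FitResult, VariancePrior, _trigamma_inverse

from ._oracles import bh_stepup_bruteforce, ols_pinv_bruteforce


def _toy_design(x: np.ndarray) -> DesignMatrix:
    n = x.shape[0]
    return DesignMatrix(
        matrix=np.column_stack([np.ones(n), x]),
        row_keys=[("R1", i) for i in range(n)],
        names=["intercept", "slope"],
        roles=["intercept", "cofactor_effect"],
    )


def _fake_fit(s2, df, A=None) -> FitResult:
    s2 = np.asarray(s2, float)
    n = s2.size
    if A is None:
        A = np.linspace(5, 12, n)
    return FitResult(
        coefficients=np.zeros((n, 1)),
        residual_variance=s2,
        residual_df=df,
        unscaled_variances=np.ones(1),
        mean_log_intensity=np.asarray(A, float),
        design=None,
        protein_ids=[f"P{i}" for i in range(n)],
    )


class TestOls:
    def test_exact_linear_fit(self):
        d = _toy_design(np.arange(4.0))
        fit = fit_linear_models(np.array([[1.0, 2.0, 3.0, 4.0]]), d)
        np.testing.assert_allclose(fit.coefficients[0], [1.0, 1.0], atol=1e-12)
        assert fit.residual_variance[0] == pytest.approx(0.0, abs=1e-20)
        assert fit.residual_df == 2

    def test_noiseless_recovery_for_any_beta(self, rng, cofactor_layout):
        d = cofactor_design(cofactor_layout)
        beta = rng.normal(size=(30, d.n_coefficients))
        fit = fit_linear_models(beta @ d.matrix.T, d)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)
        np.testing.assert_allclose(fit.residual_variance, 0.0, atol=1e-18)

    def test_matches_pseudoinverse_oracle(self, rng, cofactor_layout):
        d = cofactor_design(cofactor_layout)
        Y = rng.normal(8, 1, size=(20, d.n_observations))
        fit = fit_linear_models(Y, d)
        for g in range(20):
            beta, s2, v = ols_pinv_bruteforce(Y[g], d.matrix)
            np.testing.assert_allclose(fit.coefficients[g], beta, atol=1e-10)
            assert fit.residual_variance[g] == pytest.approx(s2, abs=1e-10)
            np.testing.assert_allclose(fit.unscaled_variances, v, atol=1e-12)
        np.testing.assert_allclose(fit.mean_log_intensity, Y.mean(axis=1), atol=1e-12)

    def test_dimension_mismatch_rejected(self, cofactor_layout, rng):
        d = cofactor_design(cofactor_layout)
        with pytest.raises(ValueError, match="observations"):
            fit_linear_models(rng.normal(size=(5, 7)), d)


class TestVariancePrior:
    def test_recovers_scaled_inverse_chisquare_parameters(self, rng):
        d0, s0, dg, n = 4.0, 0.05, 8, 5000
        sigma2 = s0 * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(dg, n) / dg
        prior = estimate_variance_prior(_fake_fit(s2, dg), trend=False)
        assert prior.prior_df == pytest.approx(d0, rel=0.15)
        assert prior.prior_variance[0] == pytest.approx(s0, rel=0.15)
        assert np.ptp(prior.prior_variance) == 0.0  # constant without trend

    def test_identical_variances_give_infinite_prior_df(self):
        prior = estimate_variance_prior(_fake_fit(np.full(200, 0.04), 8), trend=False)
        assert math.isinf(prior.prior_df)
        assert np.ptp(prior.prior_variance) == 0.0

    def test_recovers_intensity_trend(self, rng):
        d0, dg, n = 4.0, 8, 5000
        A = rng.normal(0.0, 2.0, n)
        s0A = 0.02 + 0.03 / (1.0 + np.exp(A))
        sigma2 = s0A * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(dg, n) / dg
        prior = estimate_variance_prior(_fake_fit(s2, dg, A=A), trend=True, span=0.5)
        lo, hi = np.quantile(A, [0.05, 0.95])
        central = (A >= lo) & (A <= hi)
        rel = np.abs(prior.prior_variance[central] - s0A[central]) / s0A[central]
        assert rel.max() < 0.20

    def test_trigamma_inverse_is_right_inverse(self):
        from scipy.special import polygamma

        for y in (1e-7, 0.01, 0.5, 2.0, 50.0, 1e8):
            x = _trigamma_inverse(y)
            assert float(polygamma(1, x)) == pytest.approx(y, rel=1e-6)


class TestModeratedT:
    def test_zero_prior_df_reproduces_classical_t(self, rng, cofactor_layout):
        d = cofactor_design(cofactor_layout)
        Y = rng.normal(8, 0.3, size=(50, d.n_observations))
        fit = fit_linear_models(Y, d)
        prior = VariancePrior(prior_df=0.0, prior_variance=np.ones(50), trend=False)
        st_mod = moderated_t_test(fit, prior, "cofactor")
        j = d.column_index("cofactor")
        classical = fit.coefficients[:, j] / np.sqrt(
            fit.residual_variance * fit.unscaled_variances[j]
        )
        np.testing.assert_allclose(st_mod.t, classical, atol=1e-12)
        np.testing.assert_allclose(
            st_mod.p_raw, 2 * ss.t.sf(np.abs(classical), fit.residual_df), atol=1e-12
        )

    def test_worked_posterior_variance_case(self):
        # d0 = 1, s0^2 = 1, dg = 2, sg^2 = 4  ->  (1*1 + 2*4) / (1+2) = 3
        fit = _fake_fit(np.array([4.0]), 2)
        prior = VariancePrior(prior_df=1.0, prior_variance=np.array([1.0]), trend=False)
        assert squeeze_variances(fit, prior)[0] == pytest.approx(3.0, abs=1e-12)

    def test_posterior_variance_is_convex_combination(self, rng):
        s2 = rng.chisquare(5, 300) / 50
        fit = _fake_fit(s2, 8)
        prior = VariancePrior(prior_df=3.0, prior_variance=np.full(300, 0.1), trend=False)
        post = squeeze_variances(fit, prior)
        assert (post >= np.minimum(s2, 0.1) - 1e-15).all()
        assert (post <= np.maximum(s2, 0.1) + 1e-15).all()

    def test_infinite_prior_df_limit_matches_closed_form(self, rng, cofactor_layout):
        d = cofactor_design(cofactor_layout)
        Y = rng.normal(8, 0.3, size=(40, d.n_observations))
        fit = fit_linear_models(Y, d)
        s0 = np.full(40, 0.09)
        big = moderated_t_test(fit, VariancePrior(1e8, s0, False), "cofactor")
        inf = moderated_t_test(fit, VariancePrior(math.inf, s0, False), "cofactor")
        j = d.column_index("cofactor")
        closed = fit.coefficients[:, j] / (0.3 * np.sqrt(fit.unscaled_variances[j]))
        np.testing.assert_allclose(inf.t, closed, atol=1e-12)
        np.testing.assert_allclose(big.t, closed, rtol=1e-6)
        np.testing.assert_allclose(inf.p_raw, 2 * ss.norm.sf(np.abs(closed)), atol=1e-12)
        np.testing.assert_allclose(big.p_raw, inf.p_raw, rtol=1e-4, atol=1e-12)

    def test_scaling_y_scales_effect_but_not_t(self, rng, cofactor_layout):
        d = cofactor_design(cofactor_layout)
        Y = rng.normal(8, 0.3, size=(60, d.n_observations))
        fit1 = fit_linear_models(Y, d)
        fit3 = fit_linear_models(3.0 * Y, d)
        p1 = estimate_variance_prior(fit1, trend=False)
        p3 = estimate_variance_prior(fit3, trend=False)
        st1 = moderated_t_test(fit1, p1, "cofactor")
        st3 = moderated_t_test(fit3, p3, "cofactor")
        np.testing.assert_allclose(st3.effect, 3.0 * st1.effect, rtol=1e-10)
        np.testing.assert_allclose(st3.t, st1.t, rtol=1e-8)

    def test_null_pvalues_uniform(self, rng, cofactor_layout):
        d = cofactor_design(cofactor_layout)
        n = 5000
        sigma2 = 0.05 * 4.0 / rng.chisquare(4.0, n)
        Y = 8.0 + np.sqrt(sigma2)[:, None] * rng.standard_normal((n, d.n_observations))
        fit = fit_linear_models(Y, d)
        prior = estimate_variance_prior(fit, trend=False)
        st_mod = moderated_t_test(fit, prior, "cofactor")
        assert ss.kstest(st_mod.p_raw, "uniform").pvalue > 0.01

    def test_limma_cross_check(self, rng, cofactor_layout, tmp_path):
        """Moderated t, p, prior df and prior variance agree with the
        reference empirical-Bayes implementation (limma, trend off)."""
        d = cofactor_design(cofactor_layout)
        n = 300
        beta = rng.normal(0, 0.3, size=(n, d.n_coefficients))
        sigma2 = 0.05 * 4.0 / rng.chisquare(4.0, n)
        Y = beta @ d.matrix.T + np.sqrt(sigma2)[:, None] * rng.standard_normal(
            (n, d.n_observations)
        ) + 8.0
        yf, xf, outf = tmp_path / "y.csv", tmp_path / "x.csv", tmp_path / "out.csv"
        np.savetxt(yf, Y, delimiter=",")
        np.savetxt(xf, d.matrix, delimiter=",")
        script = (
            "suppressMessages(library(limma));"
            f"y <- as.matrix(read.csv('{yf}', header=FALSE));"
            f"x <- as.matrix(read.csv('{xf}', header=FALSE));"
            "fit <- eBayes(lmFit(y, x), trend=FALSE);"
            "out <- cbind(fit$t[,2], fit$p.value[,2], fit$df.prior, fit$s2.prior);"
            f"write.table(out, '{outf}', sep=',', row.names=FALSE, col.names=FALSE)"
        )
        subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        ref = np.loadtxt(outf, delimiter=",")

        fit = fit_linear_models(Y, d)
        prior = estimate_variance_prior(fit, trend=False)
        st_mod = moderated_t_test(fit, prior, "cofactor")
        np.testing.assert_allclose(st_mod.t, ref[:, 0], rtol=1e-8)
        np.testing.assert_allclose(st_mod.p_raw, ref[:, 1], rtol=1e-6, atol=1e-12)
        assert prior.prior_df == pytest.approx(ref[0, 2], rel=1e-5)
        assert prior.prior_variance[0] == pytest.approx(ref[0, 3], rel=1e-5)


class TestBhAndCalls:
    def test_worked_five_value_example(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        np.testing.assert_allclose(adjust_bh(p), [0.05] * 5, atol=1e-12)

    def test_single_value_passthrough(self):
        np.testing.assert_allclose(adjust_bh([1.0]), [1.0])

    def test_matches_stepup_bruteforce(self, rng):
        for _ in range(20):
            p = rng.random(200)
            np.testing.assert_allclose(adjust_bh(p), bh_stepup_bruteforce(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjusted_at_least_raw_and_in_unit_interval(self, p):
        adj = adjust_bh(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])
        with pytest.raises(ValueError):
            adjust_bh([0.5, np.nan])

    def test_strictly_below_alpha_rule(self):
        calls = call_significance(np.array([0.0099, 0.01, 0.5]), alpha=0.01)
        assert calls.tolist() == [True, False, False]
        assert call_significance(np.array([0.2, 0.9]), alpha=1.0).all()
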