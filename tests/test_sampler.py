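"""Priors, Gibbs sampler contracts, and split-Rhat diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ticmediation.cohort import CohortTable
from ticmediation.pathmodel import Equation, PathModelSpec, ParameterVector
from ticmediation.sampler import (
    ConditioningError,
    PriorSpec,
    SamplerConfig,
    check_convergence,
    log_prior,
    sample_posterior,
    split_rhat,
)

from conftest import make_cohort_df


class TestLogPrior:
    def _params(self, coef=0.0, sigma=1.0, rho=0.0):
        return ParameterVector(
            coefficients={"a": coef}, intercepts={}, residual_sd={"y": sigma},
            residual_corr={("y", "z"): rho},
        )

    def test_coefficient_contributes_normal_density(self):
        base = log_prior(self._params(coef=0.0))
        shifted = log_prior(self._params(coef=3.0))
        expected = stats.norm.logpdf(3.0, 0, 10) - stats.norm.logpdf(0.0, 0, 10)
        assert shifted - base == pytest.approx(expected, abs=1e-12)

    def test_gamma_exponential_special_case(self):
        # shape 1, rate 0.5: log f(2) = log(0.5) - 1
        p = PriorSpec()
        assert p.log_sd(2.0) == pytest.approx(math.log(0.5) - 1.0, abs=1e-12)
        assert p.log_sd(2.0) == pytest.approx(stats.gamma.logpdf(2.0, a=1, scale=2.0))

    def test_correlation_prior_uniform(self):
        a = log_prior(self._params(rho=0.3))
        b = log_prior(self._params(rho=-0.8))
        assert a == pytest.approx(b, abs=1e-12)

    def test_off_support_is_minus_inf(self):
        assert log_prior(self._params(sigma=-0.5)) == -math.inf
        assert log_prior(self._params(rho=1.0)) == -math.inf


def _toy_regression_cohort(n=50, beta=0.5, intercept=10.0, sigma=2.0, seed=42):
    rng = np.random.default_rng(seed)
    x = 30 + 5 * rng.standard_normal(n)
    y = intercept + beta * x + sigma * rng.standard_normal(n)
    df = make_cohort_df([
        {"subject_id": f"S{i}", "age": 10.0, "sex": 0, "comorbidity": 0}
        for i in range(n)
    ])
    df["ygtss_total"] = x
    df["puts_total"] = y
    spec = PathModelSpec("toy", [Equation("puts_total", (("a", ("ygtss_total",)),))])
    return spec, CohortTable(df, puts_bounds=None), x, y


class TestSampler:
    def test_same_seed_identical_draws(self, unclipped_cohort):
        cfg = SamplerConfig(n_chains=2, n_warmup=20, n_draws=30, seed=5)
        d1 = sample_posterior("simplified", unclipped_cohort, config=cfg)
        d2 = sample_posterior("simplified", unclipped_cohort, config=cfg)
        for name in d1.param_names:
            np.testing.assert_array_equal(d1[name], d2[name])

    def test_different_seeds_differ(self, unclipped_cohort):
        d1 = sample_posterior("simplified", unclipped_cohort,
                              config=SamplerConfig(n_chains=1, n_warmup=20, n_draws=30, seed=5))
        d2 = sample_posterior("simplified", unclipped_cohort,
                              config=SamplerConfig(n_chains=1, n_warmup=20, n_draws=30, seed=6))
        assert not np.array_equal(d1["a1"], d2["a1"])

    def test_conjugate_oracle_known_sigma(self):
        spec, cohort, x, y = _toy_regression_cohort()
        sigma = 2.0
        cfg = SamplerConfig(n_chains=2, n_warmup=100, n_draws=2500, seed=7,
                            fixed={"sigma_puts_total": sigma})
        draws = sample_posterior(spec, cohort, PriorSpec(), cfg)
        X = np.column_stack([np.ones(len(x)), x])
        # prior: intercept ~ N(0, 100), slope ~ N(0, 10)
        prec = X.T @ X / sigma**2 + np.diag([1 / 100.0**2, 1 / 10.0**2])
        mean = np.linalg.solve(prec, X.T @ y / sigma**2)
        cov = np.linalg.inv(prec)
        for i, name in enumerate(["intercept_puts_total", "a"]):
            mc = draws.pooled(name)
            se = math.sqrt(cov[i, i] / mc.size)
            assert abs(mc.mean() - mean[i]) < 4 * se
            assert mc.std(ddof=1) == pytest.approx(math.sqrt(cov[i, i]), rel=0.05)

    def test_every_draw_satisfies_domain_invariants(self, fitted_results):
        draws = fitted_results.draws
        for name in draws.param_names:
            arr = draws[name]
            if name.startswith("sigma_"):
                assert (arr > 0).all()
            if name.startswith("rho_"):
                assert (np.abs(arr) < 1).all()

    def test_prior_only_reproduces_prior_moments(self, unclipped_cohort):
        cfg = SamplerConfig(n_chains=2, n_draws=20000, seed=1, prior_only=True)
        draws = sample_posterior("simplified", unclipped_cohort, config=cfg)
        assert draws.pooled("a1").std(ddof=1) == pytest.approx(10.0, rel=0.03)
        assert draws.pooled("intercept_mi_raw").std(ddof=1) == pytest.approx(100.0, rel=0.03)
        assert draws.pooled("sigma_bri_raw").mean() == pytest.approx(2.0, rel=0.03)
        rho = draws.pooled("rho_bri_raw_mi_raw")
        assert rho.mean() == pytest.approx(0.0, abs=0.02)
        assert rho.var() == pytest.approx(1.0 / 3.0, rel=0.05)
        assert stats.kstest(rho, stats.uniform(-1, 2).cdf).pvalue > 0.01

    def test_data_augmentation_handles_missing_outcomes(self, unclipped_cohort):
        df = unclipped_cohort.df.copy()
        rng = np.random.default_rng(3)
        for col in ("puts_total", "bri_raw", "mi_raw"):
            df.loc[rng.choice(len(df), 10, replace=False), col] = np.nan
        cohort = unclipped_cohort.with_df(df)
        cfg = SamplerConfig(n_chains=2, n_warmup=100, n_draws=200, seed=9)
        draws = sample_posterior("simplified", cohort, config=cfg)
        assert draws.diagnostics["n_partial_subjects"] > 0
        assert check_convergence(draws, threshold=1.2).passed

    def test_collinear_design_raises_informative_error(self):
        spec = PathModelSpec(
            "collinear",
            [Equation("puts_total", (("a", ("ygtss_total",)), ("b", ("ygtss_total",))))],
        )
        _, cohort, _, _ = _toy_regression_cohort()
        with pytest.raises(ConditioningError, match="collinear"):
            sample_posterior(spec, cohort, config=SamplerConfig(n_chains=1, n_warmup=5, n_draws=5))

    def test_only_residual_parameters_may_be_fixed(self, unclipped_cohort):
        with pytest.raises(ValueError, match="fixed"):
            sample_posterior("simplified", unclipped_cohort,
                             config=SamplerConfig(fixed={"a1": 0.0}))


class TestSplitRhat:
    def test_interleaved_well_mixed_stream_near_one(self):
        stream = np.random.default_rng(0).standard_normal(4000)
        chains = np.stack([stream[0::2], stream[1::2]])
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.standard_normal(500), rng.standard_normal(500) + 5.0])
        assert split_rhat(chains) > 1.05

    def test_constant_chains_undefined(self):
        chains = np.full((2, 100), 3.0)
        assert math.isnan(split_rhat(chains))

    def test_matches_arviz_split_method(self):
        import arviz as az

        rng = np.random.default_rng(2)
        for offset in (0.0, 0.5, 2.0):
            chains = np.stack([rng.standard_normal(400),
                               rng.standard_normal(400) + offset])
            ours = split_rhat(chains)
            theirs = float(az.rhat(az.from_dict(posterior={"x": chains}),
                                   method="split").x)
            assert ours == pytest.approx(theirs, rel=1e-10)

    def test_requires_minimum_shape(self):
        with pytest.raises(ValueError):
            split_rhat(np.zeros((1, 100)))


class TestConvergenceReport:
    def test_pass_and_fail_naming(self, fitted_results):
        report = fitted_results.convergence(threshold=1.05)
        assert report.passed
        assert not report.failing
        strict = fitted_results.convergence(threshold=1.0)
        assert not strict.passed
        assert strict.failing  # names the offending parameters

    def test_fail_names_parameter(self):
        from ticmediation.sampler import PosteriorDraws
        from ticmediation.pathmodel import simplified_moderated_spec

        spec = simplified_moderated_spec()
        rng = np.random.default_rng(0)
        arrays = {}
        names = ([f"intercept_{o}" for o in spec.outcomes] + spec.path_labels
                 + [f"sigma_{o}" for o in spec.outcomes] + ["rho_bri_raw_mi_raw"])
        for name in names:
            arrays[name] = rng.standard_normal((2, 200))
        arrays["a4"] = np.stack([rng.standard_normal(200), rng.standard_normal(200) + 8])
        draws = PosteriorDraws(spec, arrays, SamplerConfig(n_chains=2, n_draws=200))
        report = check_convergence(draws)
        assert not report.passed
        assert report.failing == ["a4"]
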