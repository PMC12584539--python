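"""Synthetic cohort generator: determinism, marginals, structure."""

import io

import numpy as np
import pytest
from scipy import stats

from ticmediation import GeneratorConfig, generate_cohort
from ticmediation import simulate as sim
from ticmediation.pathmodel import design_matrix, simplified_moderated_spec
from ticmediation.simulate import (
    ConfigurationError,
    apply_missingness,
    generate_covariates,
    generate_outcomes,
    solve_intercepts,
    truncnorm_underlying,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n": 0},
            {"prevalence_comorbidity": 1.5},
            {"missing_rate": -0.1},
            {"age_sd": -1.0},
            {"age_bounds": (16.0, 6.0)},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(**kw).validate()

    def test_yaml_round_trip(self):
        cfg = GeneratorConfig(n=42, seed=9, missing_rate=0.01, clip_outcomes=False)
        back = GeneratorConfig.from_yaml(io.StringIO(cfg.to_yaml()))
        assert back == cfg

    def test_yaml_round_trip_with_explicit_truth(self):
        cfg = GeneratorConfig(truth=GeneratorConfig().resolve_truth())
        back = GeneratorConfig.from_yaml(io.StringIO(cfg.to_yaml()))
        assert back.truth.coefficients == cfg.truth.coefficients
        assert back.truth.residual_corr == cfg.truth.residual_corr


class TestCovariates:
    def test_seed_determinism(self):
        cfg = GeneratorConfig(n=1, seed=123)
        a = generate_covariates(cfg).df
        b = generate_covariates(cfg).df
        assert a.equals(b)

    def test_degenerate_bernoulli(self):
        cfg = GeneratorConfig(n=200, seed=3, prevalence_comorbidity=0.0)
        df = generate_covariates(cfg).df
        assert (df["comorbidity"] == 0.0).all()

    def test_truncated_age_matches_moment_oracle(self):
        cfg = GeneratorConfig(n=50000, seed=11)
        df = generate_covariates(cfg).df
        # the configured mean is the post-truncation target ...
        assert abs(df["age"].mean() - cfg.age_mean) < 0.05
        # ... and equals the truncated-normal moment at the solved params
        loc, scale = truncnorm_underlying(cfg.age_mean, cfg.age_sd, cfg.age_bounds)
        a, b = (cfg.age_bounds[0] - loc) / scale, (cfg.age_bounds[1] - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        assert float(m) == pytest.approx(cfg.age_mean, abs=1e-6)
        se = np.sqrt(float(v) / cfg.n)
        assert abs(df["age"].mean() - float(m)) < 3 * se
        assert df["age"].between(*cfg.age_bounds).all()

    def test_comorbidity_severity_dependence_shift(self):
        # group-shifted means need a slightly smaller spread to stay
        # attainable inside the instrument range
        cfg = GeneratorConfig(n=40000, seed=13, ygtss_comorbidity_shift=6.0,
                              ygtss_sd=10.0)
        df = generate_covariates(cfg).df
        gm = df.groupby("comorbidity")["ygtss_total"].mean()
        assert gm[1.0] - gm[0.0] == pytest.approx(6.0, abs=0.5)
        assert df["ygtss_total"].mean() == pytest.approx(cfg.ygtss_mean, abs=0.3)


class TestOutcomes:
    def test_near_zero_noise_returns_linear_predictor(self):
        cfg = GeneratorConfig(n=20, seed=5)
        cov = generate_covariates(cfg)
        spec = simplified_moderated_spec()
        truth = cfg.resolve_truth()
        for o in truth.residual_sd:
            truth.residual_sd[o] = 1e-9
        truth = solve_intercepts(spec, truth, sim.covariate_means(cfg))
        out = generate_outcomes(cov, truth, spec, seed=1)
        for o in spec.outcomes:
            eq = spec.equation(o)
            expected = design_matrix(out.df, eq) @ np.concatenate(
                [[truth.intercepts[o]], [truth.coefficients[l] for l, _ in eq.terms]]
            )
            np.testing.assert_allclose(out.df[o], expected, atol=1e-6)

    def test_gec_equals_bri_plus_mi(self, default_cohort):
        df = default_cohort.df.dropna(subset=["bri_raw", "mi_raw", "gec_raw"])
        np.testing.assert_allclose(df["gec_raw"], df["bri_raw"] + df["mi_raw"], atol=1e-9)

    def test_residual_correlation_recovered(self):
        cfg = GeneratorConfig(n=50000, seed=2, clip_outcomes=False, missing_rate=0.0)
        cohort = generate_cohort(cfg)
        spec = simplified_moderated_spec()
        df = cohort.df
        resid = {}
        for o in ("bri_raw", "mi_raw"):
            X = design_matrix(df, spec.equation(o))
            resid[o] = df[o] - X @ np.linalg.lstsq(X, df[o], rcond=None)[0]
        r = np.corrcoef(resid["bri_raw"], resid["mi_raw"])[0, 1]
        assert r == pytest.approx(0.707, abs=0.01)

    def test_solved_intercepts_hit_marginal_means(self):
        from ticmediation.calibration import COHORT_MARGINALS

        cfg = GeneratorConfig(n=50000, seed=8, clip_outcomes=False, missing_rate=0.0)
        df = generate_cohort(cfg).df
        for col, key in [("puts_total", "puts_mean"), ("bri_raw", "bri_mean"),
                         ("mi_raw", "mi_mean")]:
            se = df[col].std() / np.sqrt(len(df))
            assert abs(df[col].mean() - COHORT_MARGINALS[key]) < 4 * se

    def test_clipping_flagged_and_in_range(self):
        cfg = GeneratorConfig(n=500, seed=6)  # clip_outcomes defaults on
        cohort = generate_cohort(cfg)
        assert "clipped" in cohort.provenance
        assert cohort.df["puts_total"].dropna().between(9, 36).all()

    def test_unclipped_cohort_carries_relaxed_bounds(self, unclipped_cohort):
        assert unclipped_cohort.puts_bounds is None
        assert "unclipped" in unclipped_cohort.provenance

    def test_rounding_produces_integer_scores(self):
        cfg = GeneratorConfig(n=50, seed=4, round_scores=True)
        df = generate_cohort(cfg).df
        vals = df["puts_total"].dropna()
        np.testing.assert_allclose(vals, np.round(vals))

    def test_dimension_mismatch_raises(self):
        cfg = GeneratorConfig(n=10, seed=5)
        cov = generate_covariates(cfg)
        truth = cfg.resolve_truth()
        del truth.coefficients["a4"]
        with pytest.raises(Exception, match="a4"):
            generate_outcomes(cov, truth, "simplified", seed=1)


class TestMissingness:
    def test_rate_zero_is_identity(self, default_cohort):
        out = apply_missingness(default_cohort, 0.0, seed=1)
        assert out.df.equals(default_cohort.df)

    def test_rate_one_rejected(self, default_cohort):
        with pytest.raises(ConfigurationError):
            apply_missingness(default_cohort, 1.0, seed=1)

    def test_rate_matches_binomial_oracle(self):
        cfg = GeneratorConfig(n=10000, seed=30, missing_rate=0.0, clip_outcomes=False)
        cohort = generate_cohort(cfg)
        rate = 0.01
        out = apply_missingness(cohort, rate, seed=31)
        cells = 4 * len(out)  # puts, bri, mi, gec are eligible
        n_missing = int(out.df[["puts_total", "bri_raw", "mi_raw", "gec_raw"]].isna().sum().sum())
        se = np.sqrt(rate * (1 - rate) * cells)
        assert abs(n_missing - rate * cells) < 3 * se

    def test_exogenous_protected_by_default(self):
        cfg = GeneratorConfig(n=2000, seed=40, missing_rate=0.2)
        df = generate_cohort(cfg).df
        assert df[["age", "sex", "comorbidity", "ygtss_total"]].notna().all().all()
        assert df["puts_total"].isna().any()


def test_full_pipeline_determinism(tmp_path):
    from ticmediation.cohort import write_cohort

    cfg = GeneratorConfig(n=120, seed=55, missing_rate=0.02)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cohort(generate_cohort(cfg), p1)
    write_cohort(generate_cohort(cfg), p2)
    assert p1.read_bytes() == p2.read_bytes()
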