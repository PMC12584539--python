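"""Path model specs, the text grammar, and the exact likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ticmediation import simulate as sim
from ticmediation.cohort import CohortTable
from ticmediation.pathmodel import (
    Equation,
    ModelError,
    ParameterVector,
    PathModelSpec,
    evaluate_defined,
    full_moderated_spec,
    log_likelihood,
    simple_mediation_spec,
    simplified_moderated_spec,
    subject_joint_mvn,
)

from conftest import make_cohort_df


class TestSpecs:
    def test_simple_mediation_labels(self):
        spec = simple_mediation_spec()
        assert {"a", "b", "c_prime"} <= set(spec.path_labels)
        assert spec.defined_parameters["indirect"] == "a*b"
        assert evaluate_defined(spec, {l: 0.0 for l in spec.path_labels})["indirect"] == 0.0

    def test_simplified_label_set_matches_report_rows(self):
        spec = simplified_moderated_spec()
        assert set(spec.path_labels) == {
            "a1", "a2", "a4",
            "b1", "b2", "b3", "b4", "b5",
            "c1", "c2", "c3", "c4", "c5",
        }
        assert spec.residual_correlation_pairs == [("bri_raw", "mi_raw")]
        # the mediator equation has no comorbidity main effect and no sex term
        puts_vars = {v for _, t in spec.equation("puts_total").terms for v in t}
        assert "sex" not in puts_vars
        assert ("comorbidity",) not in [t for _, t in spec.equation("puts_total").terms]

    def test_imm_is_difference_of_conditional_indirects(self):
        spec = simplified_moderated_spec()
        rng = np.random.default_rng(0)
        for _ in range(25):
            coefs = {l: rng.normal() for l in spec.path_labels}
            d = evaluate_defined(spec, coefs)
            assert d["imm_bri"] == pytest.approx(d["ie_bri_c1"] - d["ie_bri_c0"], abs=1e-12)
            assert d["imm_mi"] == pytest.approx(d["ie_mi_c1"] - d["ie_mi_c0"], abs=1e-12)

    def test_full_model_nests_simplified(self):
        full, simp = full_moderated_spec(), simplified_moderated_spec()
        assert set(simp.path_labels) < set(full.path_labels)
        for eq in simp.equations:
            full_terms = {t for _, t in full.equation(eq.outcome).terms}
            assert {t for _, t in eq.terms} <= full_terms
        # interaction on the mediator ('a') path present
        assert ("ygtss_total", "comorbidity") in {
            t for _, t in full.equation("puts_total").terms
        }
        # moderation probed on the outcome stages too
        assert ("puts_total", "comorbidity") in {
            t for _, t in full.equation("bri_raw").terms
        }

    def test_triangularity_violation_rejected(self):
        with pytest.raises(ModelError, match="triangularity"):
            PathModelSpec(
                "bad",
                [Equation("puts_total", (("x", ("bri_raw",)),)),
                 Equation("bri_raw", (("y", ("age",)),))],
            )

    def test_correlated_outcomes_must_not_predict_each_other(self):
        with pytest.raises(ModelError, match="may not predict"):
            PathModelSpec(
                "bad",
                [Equation("bri_raw", (("x", ("age",)),)),
                 Equation("mi_raw", (("y", ("bri_raw",)),))],
                [("bri_raw", "mi_raw")],
            )

    def test_unknown_label_in_defined_parameter_rejected(self):
        with pytest.raises(ModelError, match="unknown label"):
            PathModelSpec(
                "bad",
                [Equation("puts_total", (("a", ("age",)),))],
                defined_parameters={"ie": "a*zz"},
            )

    def test_text_grammar_round_trip(self):
        for factory in (simple_mediation_spec, simplified_moderated_spec, full_moderated_spec):
            spec = factory()
            back = PathModelSpec.from_text(spec.to_text(), spec.name)
            assert back.equations == spec.equations
            assert back.residual_correlation_pairs == spec.residual_correlation_pairs
            assert back.defined_parameters == spec.defined_parameters
            assert back.moderators == spec.moderators


def _toy_params(spec, **overrides):
    params = ParameterVector(
        coefficients={l: 0.5 for l in spec.path_labels},
        intercepts={o: 1.0 for o in spec.outcomes},
        residual_sd={o: 2.0 for o in spec.outcomes},
        residual_corr={tuple(p): 0.4 for p in spec.residual_correlation_pairs},
    )
    for k, v in overrides.items():
        setattr(params, k, v)
    return params


class TestLikelihood:
    def test_single_subject_closed_form_normal(self):
        spec = PathModelSpec("toy", [Equation("puts_total", (("a", ("ygtss_total",)),))])
        params = _toy_params(spec)
        df = make_cohort_df([
            {"subject_id": "S1", "age": 9.0, "sex": 0, "comorbidity": 0,
             "ygtss_total": 20.0, "puts_total": 14.0},
        ])
        cohort = CohortTable(df)
        expected = stats.norm.logpdf(14.0, loc=1.0 + 0.5 * 20.0, scale=2.0)
        assert log_likelihood(spec, params, cohort) == pytest.approx(expected, abs=1e-10)

    def test_zero_residual_correlation_factorizes(self, unclipped_cohort, unclipped_truth):
        spec = simplified_moderated_spec()
        params = unclipped_truth.copy()
        params.residual_corr[("bri_raw", "mi_raw")] = 1e-14
        joint = log_likelihood(spec, params, unclipped_cohort)

        # sum of three univariate stages
        split = PathModelSpec(
            spec.name + "_indep", spec.equations, [], dict(spec.defined_parameters),
            list(spec.moderators),
        )
        params2 = params.copy()
        params2.residual_corr = {}
        assert joint == pytest.approx(log_likelihood(split, params2, unclipped_cohort), rel=1e-12)

    def test_complete_data_fiml_equals_joint_density(self, unclipped_cohort, unclipped_truth):
        spec = simplified_moderated_spec()
        df = unclipped_cohort.df.dropna(subset=spec.outcomes)
        factorized = log_likelihood(spec, unclipped_truth, df)
        total = 0.0
        outs = spec.outcomes
        for _, row in df.iterrows():
            mean, cov = subject_joint_mvn(spec, unclipped_truth, row)
            x = row[outs].to_numpy(dtype=float)
            total += stats.multivariate_normal.logpdf(x, mean=mean, cov=cov)
        assert factorized == pytest.approx(total, rel=1e-10)

    def test_missing_outcome_marginalized(self, unclipped_truth):
        # subject observed on urge and BRI only: contribution is
        # p(urge | x) * p(BRI | urge, x) with BRI's own residual SD,
        # the MI coordinate integrating out of the bivariate stage
        spec = simplified_moderated_spec()
        df = make_cohort_df([
            {"subject_id": "S1", "age": 9.0, "sex": 1, "comorbidity": 1,
             "ygtss_total": 31.0, "puts_total": 16.0, "bri_raw": 52.0},
        ])
        t = unclipped_truth
        ll = log_likelihood(spec, t, CohortTable(df))
        lp_puts = (
            t.intercepts["puts_total"]
            + t.coefficients["a1"] * 31.0
            + t.coefficients["a2"] * 9.0
            + t.coefficients["a4"] * 31.0 * 1.0
        )
        lp_bri = (
            t.intercepts["bri_raw"]
            + t.coefficients["b1"] * 16.0
            + t.coefficients["b2"] * 31.0
            + t.coefficients["b3"] * 9.0
            + t.coefficients["b4"] * 1.0
            + t.coefficients["b5"] * 1.0
        )
        expected = stats.norm.logpdf(16.0, lp_puts, t.residual_sd["puts_total"]) + \
            stats.norm.logpdf(52.0, lp_bri, t.residual_sd["bri_raw"])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_subject_order_invariance(self, unclipped_cohort, unclipped_truth):
        spec = simplified_moderated_spec()
        shuffled = unclipped_cohort.df.sample(frac=1.0, random_state=1)
        assert log_likelihood(spec, unclipped_truth, unclipped_cohort) == pytest.approx(
            log_likelihood(spec, unclipped_truth, shuffled), rel=1e-12
        )

    def test_missing_exogenous_subjects_dropped_with_count(self, unclipped_truth):
        spec = simplified_moderated_spec()
        df = make_cohort_df([
            {"subject_id": "S1", "age": 9.0, "sex": 0, "comorbidity": 0,
             "ygtss_total": 25.0, "puts_total": 13.0, "bri_raw": 45.0, "mi_raw": 88.0,
             "gec_raw": 133.0},
            {"subject_id": "S2", "age": 10.0, "sex": 0, "comorbidity": None,
             "ygtss_total": 25.0, "puts_total": 13.0, "bri_raw": 45.0, "mi_raw": 88.0,
             "gec_raw": 133.0},
        ])
        ll, dropped = log_likelihood(spec, unclipped_truth, CohortTable(df), return_dropped=True)
        assert dropped == 1
        assert math.isfinite(ll)

    def test_truth_beats_perturbations(self, unclipped_cohort, unclipped_truth):
        spec = simplified_moderated_spec()
        ll_truth = log_likelihood(spec, unclipped_truth, unclipped_cohort)
        rng = np.random.default_rng(0)
        for _ in range(5):
            pert = unclipped_truth.copy()
            pert.coefficients = {
                k: v + rng.normal(0, 0.2 + 0.2 * abs(v))
                for k, v in pert.coefficients.items()
            }
            assert log_likelihood(spec, pert, unclipped_cohort) < ll_truth

    def test_invalid_params_rejected(self):
        spec = simple_mediation_spec()
        params = _toy_params(spec)
        params.residual_sd["gec_raw"] = -1.0
        with pytest.raises(ModelError, match="residual SD"):
            params.validate(spec)
        params2 = _toy_params(spec)
        params2.residual_corr[("x", "y")] = 1.5
        with pytest.raises(ModelError, match="correlation"):
            params2.validate()
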