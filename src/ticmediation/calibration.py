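"""Default calibration for the synthetic cohort generator.

Marginal summaries and structural path coefficients representative of a
school-age tic-disorder clinic population (n ≈ 154, mostly boys, roughly
half with a comorbid diagnosis).  These constants serve two roles:

* defaults for :class:`ticmediation.simulate.GeneratorConfig`, so that a
  freshly generated cohort has realistic locations, spreads and effect
  sizes without any download; and
* the ground truth against which parameter-recovery tests and the
  point-estimate mediation algebra (conditional indirect effects, index
  of moderated mediation, standardized composites) are evaluated.

Instrument scales: YGTSS total tic severity 0-50, PUTS urge total 9-36,
BRIEF raw composites (BRI + MI = GEC).
"""

from __future__ import annotations

from .pathmodel import (
    ParameterVector,
    simple_mediation_spec,
    simplified_moderated_spec,
)

#: cohort marginal targets (means / SDs on raw instrument scales)
COHORT_MARGINALS = {
    "n": 154,
    "prevalence_female": 24 / 154,        # 15.58 %
    "prevalence_comorbidity": 82 / 154,   # 53.25 %
    "age_mean": 9.29,
    "age_sd": 1.95,
    "ygtss_mean": 32.71,
    "ygtss_sd": 13.17,
    "puts_mean": 14.47,
    "puts_sd": 4.58,
    "bri_mean": 47.92,
    "bri_sd": 10.88,
    "mi_mean": 90.18,
    "mi_sd": 15.38,
    "gec_mean": 138.10,
    "gec_sd": 24.34,
}

#: moderated-mediation structural truth: path coefficients, residual SDs
#: (variances 16.081 / 114.014 / 218.552) and the BRI-MI residual
#: correlation (covariance 111.551 -> rho ≈ 0.707).  Intercepts are solved
#: at generation time so linear predictors hit the marginal means.
SIMPLIFIED_TRUTH_COEFFICIENTS = {
    "a1": 0.094,   # severity -> urge, non-comorbid slope
    "a2": 0.207,   # age -> urge
    "a4": 0.061,   # severity x comorbidity -> urge (moderation)
    "b1": 0.592,   # urge -> BRI
    "b2": 0.196,   # severity -> BRI (direct)
    "b3": 0.800,   # age -> BRI
    "b4": 1.043,   # sex -> BRI
    "b5": 4.095,   # comorbidity -> BRI
    "c1": 1.175,   # urge -> MI
    "c2": 0.127,   # severity -> MI (direct)
    "c3": 1.249,   # age -> MI
    "c4": -2.179,  # sex -> MI
    "c5": 8.343,   # comorbidity -> MI
}

SIMPLIFIED_RESIDUAL_VARIANCES = {
    "puts_total": 16.081,
    "bri_raw": 114.014,
    "mi_raw": 218.552,
}

SIMPLIFIED_RESIDUAL_COVARIANCE_BRI_MI = 111.551

#: fully standardized (std.all) path values on the same calibration
SIMPLIFIED_TRUTH_STD = {
    "a1": 0.272,
    "a2": 0.089,
    "a4": 0.262,
    "b1": 0.224,
    "b2": 0.214,
    "b3": 0.129,
    "b4": 0.031,
    "b5": 0.170,
    "c1": 0.308,
    "c2": 0.096,
    "c3": 0.140,
    "c4": -0.046,
    "c5": 0.240,
}

#: simple-mediation calibration (urge mediates severity -> GEC)
SIMPLE_TRUTH_COEFFICIENTS = {
    "a": 0.130,
    "a_age": 0.0,
    "a_sex": 0.0,
    "a_comorbidity": 1.644,
    "b": 1.082,
    "c_prime": 0.188,
    "b_age": 0.0,
    "b_sex": 0.0,
    "b_comorbidity": 10.992,
}

SIMPLE_TRUTH_STD = {"a": 0.377, "b": 0.205, "c_prime": 0.103}


def simplified_truth() -> ParameterVector:
    """Default :class:`ParameterVector` for the simplified moderated model.

    Intercepts are placeholders (0); the generator replaces them via
    :func:`ticmediation.simulate.solve_intercepts`.
    """
    var = SIMPLIFIED_RESIDUAL_VARIANCES
    rho = SIMPLIFIED_RESIDUAL_COVARIANCE_BRI_MI / (
        (var["bri_raw"] * var["mi_raw"]) ** 0.5
    )
    spec = simplified_moderated_spec()
    return ParameterVector(
        coefficients=dict(SIMPLIFIED_TRUTH_COEFFICIENTS),
        intercepts={o: 0.0 for o in spec.outcomes},
        residual_sd={o: var[o] ** 0.5 for o in spec.outcomes},
        residual_corr={("bri_raw", "mi_raw"): rho},
    )


def simple_truth(gec_residual_sd: float = 20.0) -> ParameterVector:
    """Default :class:`ParameterVector` for the simple mediation model.

    The GEC residual SD is not part of the calibration set; 20 raw-score
    points (≈ 0.8 of the marginal GEC SD) is a realistic default for a
    model explaining a modest share of the variance.
    """
    spec = simple_mediation_spec()
    return ParameterVector(
        coefficients=dict(SIMPLE_TRUTH_COEFFICIENTS),
        intercepts={o: 0.0 for o in spec.outcomes},
        residual_sd={
            "puts_total": SIMPLIFIED_RESIDUAL_VARIANCES["puts_total"] ** 0.5,
            "gec_raw": gec_residual_sd,
        },
        residual_corr={},
    )
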