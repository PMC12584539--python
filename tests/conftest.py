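"""Shared fixtures: small synthetic cohorts and one reusable fitted model."""

import numpy as np
import pandas as pd
import pytest

from ticmediation import (
    BayesianPathModel,
    CohortTable,
    GeneratorConfig,
    generate_cohort,
)
from ticmediation import simulate as sim
from ticmediation.cohort import COLUMNS
from ticmediation.sampler import SamplerConfig


def make_cohort_df(rows):
    """Build a canonical cohort DataFrame from dicts (None = missing)."""
    df = pd.DataFrame(rows)
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[COLUMNS]


VALID_ROWS = [
    {"subject_id": "S1", "age": 8.0, "sex": 0, "comorbidity": 1,
     "ygtss_total": 30.0, "puts_total": 15.0, "bri_raw": 50.0,
     "mi_raw": 90.0, "gec_raw": 140.0},
    {"subject_id": "S2", "age": 11.5, "sex": 1, "comorbidity": 0,
     "ygtss_total": 22.0, "puts_total": 12.0, "bri_raw": 40.0,
     "mi_raw": 80.0, "gec_raw": 120.0},
    {"subject_id": "S3", "age": 9.0, "sex": 0, "comorbidity": 0,
     "ygtss_total": 45.0, "puts_total": None, "bri_raw": None,
     "mi_raw": 95.0, "gec_raw": None},
]


@pytest.fixture
def tiny_cohort():
    return CohortTable(make_cohort_df(VALID_ROWS), provenance="fixture")


@pytest.fixture(scope="session")
def default_cohort():
    """Calibrated cohort at the default study conditions (n = 154)."""
    return generate_cohort(GeneratorConfig(seed=1234))


@pytest.fixture(scope="session")
def unclipped_cohort():
    """Model-family-exact cohort for likelihood/recovery work."""
    cfg = GeneratorConfig(n=400, seed=77, clip_outcomes=False)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def unclipped_truth():
    cfg = GeneratorConfig(n=400, seed=77, clip_outcomes=False)
    spec = sim.get_model_spec(cfg.model)
    return sim.solve_intercepts(spec, cfg.resolve_truth(), sim.covariate_means(cfg))


@pytest.fixture(scope="session")
def fitted_results(unclipped_cohort):
    """One short simplified-model fit shared across summary/PPP tests."""
    model = BayesianPathModel(unclipped_cohort, model="simplified")
    return model.fit(config=SamplerConfig(n_chains=2, n_warmup=200, n_draws=500, seed=42))
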