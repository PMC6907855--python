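import numpy as np
import pandas as pd
import pytest

from vipermass import synth
from vipermass.encounter import SurveyRecord


@pytest.fixture(scope="session")
def landscape():
    return synth.generate_landscape(seed=42, shape=(40, 50), n_covariates=4,
                                    n_districts=12)


@pytest.fixture(scope="session")
def truth():
    return synth.SyntheticTruth(seed=42)


@pytest.fixture()
def survey_records():
    """Hand-built records whose pooled national counts match the field
    campaign: 85 focal vipers among 186 snakes over 562 person-hours."""
    return [
        SurveyRecord("p_low", 0, 0, 120.0, 30, 40, 60),
        SurveyRecord("p_mid", 0, 1, 90.0, 14, 18, 30),
        SurveyRecord("p_high", 0, 2, 70.0, 3, 6, 12),
        SurveyRecord("c_low", 1, 0, 130.0, 25, 33, 48),
        SurveyRecord("c_mid", 1, 1, 92.0, 10, 17, 24),
        SurveyRecord("c_high", 1, 2, 60.0, 3, 7, 12),
    ]


@pytest.fixture()
def district_table():
    """Noiseless mass-action table: I = 0.47 + 1e-3 * F * S exactly."""
    rng = np.random.default_rng(7)
    n = 40
    S = rng.lognormal(8.0, 1.0, size=n).round()
    F = rng.uniform(0, 0.3, size=n)
    return pd.DataFrame({
        "district_id": np.arange(n),
        "rural_pop": S,
        "F": F,
        "observed_incidence": 0.47 + 1e-3 * F * S,
    })


def make_noisy_table(seed, n=200, theta=1e-3, alpha=0.47, target_r2=0.66):
    truth = synth.SyntheticTruth(theta=theta, alpha=alpha, seed=seed)
    return synth.make_district_table(seed, n_districts=n, truth=truth,
                                     target_r2=target_r2)
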