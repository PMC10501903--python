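import numpy as np
import pandas as pd
import pytest

import twostep as ts


@pytest.fixture(scope="session")
def biofinder_cfg():
    return ts.biofinder_like(seed=11)


@pytest.fixture(scope="session")
def cohort(biofinder_cfg):
    return ts.generate_cohort(biofinder_cfg)


@pytest.fixture(scope="session")
def fitted_model(cohort):
    return ts.fit_logistic(cohort, ts.default_predictor_spec())


@pytest.fixture(scope="session")
def probabilities(fitted_model, cohort):
    return fitted_model.predict(cohort)


def logistic_cohort(beta0, beta_logptau, beta_age, beta_apoe, n, seed):
    """Cohort whose outcome is drawn from a known logistic model, for
    parameter-recovery and calibration tests."""
    rng = np.random.default_rng(seed)
    # geometric mean chosen so the stated coefficients give a moderate
    # outcome prevalence (linear predictor centred near 0)
    ptau = np.exp(rng.normal(np.log(3.5), 0.6, n))
    age = rng.normal(71, 6, n)
    apoe = (rng.random(n) < 0.5).astype(float)
    lp = beta0 + beta_logptau * np.log(ptau) + beta_age * age + beta_apoe * apoe
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))
    return pd.DataFrame(
        {
            "id": [str(i) for i in range(n)],
            "ptau217": ptau,
            "age": age,
            "apoe4": apoe.astype(bool),
            "abeta_pet_positive": y,
        }
    )
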