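import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_psychometric_trials(mu, sigma, n, rng,
                             grid=(-6, -4, -2, -1, 1, 2, 4, 6)):
    """Bernoulli responses from a cumulative-Gaussian observer."""
    x = rng.choice(np.asarray(grid, float), size=n)
    p = norm.cdf((x - mu) / sigma)
    y = (rng.uniform(size=n) < p).astype(int)
    return x, y


@pytest.fixture(scope="session")
def exp2_feature_pool():
    """Cue rows from a small simulated causality-judgement conflict design.

    Shared across tests that need realistic covariate distributions
    without regenerating sequences each time.
    """
    from avcausal.sequences import generate_exp2_trial
    from avcausal.features import max_click_flash_offset, \
        proportion_synchronous

    rng = np.random.default_rng(777)
    rows = []
    for rate in (8, 10, 12, 14):
        for _ in range(400):
            pair = generate_exp2_trial(rate, 2000, temporal_conflict=True,
                                       rng=rng)
            rows.append((rate,
                         proportion_synchronous(pair),
                         max_click_flash_offset(pair) / 1000.0))
    return pd.DataFrame(rows, columns=["rate_hz", "prop_sync",
                                       "max_offset_s"])


def make_glmm_table(pool, beta, tau, n_subjects, n_per_subject, rng):
    """Sample covariates from the pool, draw responses from the logistic
    random-intercept model."""
    from scipy.special import expit

    b0, b_sync, b_off, b_int = beta
    u = rng.normal(0.0, tau, size=n_subjects)
    idx = rng.integers(0, len(pool), size=n_subjects * n_per_subject)
    sub = pool.iloc[idx].reset_index(drop=True)
    table = pd.DataFrame({
        "subject": np.repeat(np.arange(n_subjects), n_per_subject),
        "rate_hz": sub["rate_hz"].to_numpy(),
        "prop_sync": sub["prop_sync"].to_numpy(),
        "max_offset_s": sub["max_offset_s"].to_numpy(),
    })
    eta = (b0 + b_sync * table["prop_sync"] + b_off * table["max_offset_s"]
           + b_int * table["prop_sync"] * table["max_offset_s"]
           + u[table["subject"]])
    table["response_common"] = (
        rng.uniform(size=len(table)) < expit(eta)).astype(int)
    return table
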