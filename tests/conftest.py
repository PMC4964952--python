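import numpy as np
import pandas as pd
import pytest

from cengrm import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_survey(
    n=20,
    seed=0,
    censor_every=4,
    tau=0.5,
    geology=("dsd", "dsl", "dt"),
):
    """Tiny valid survey+covariate pair for I/O and design tests."""
    r = np.random.default_rng(seed)
    value = np.round(np.exp(r.normal(2.0, 1.0, n)) + tau, 3)
    delta = np.ones(n, int)
    if censor_every:
        delta[::censor_every] = 0
    survey = pd.DataFrame({
        "site_id": [f"W{i:03d}" for i in range(n)],
        "lon": np.round(r.uniform(88.2, 92.4, n), 5),
        "lat": np.round(r.uniform(21.0, 26.4, n), 5),
        "depth": np.round(r.uniform(5, 50, n), 1),
        "date": pd.to_datetime("1998-01-01") + pd.to_timedelta(
            r.integers(0, 700, n), unit="D"),
        "value": np.where(delta == 1, value, np.nan),
        "delta": delta,
        "tau": np.where(delta == 0, tau, np.nan),
    })
    survey["date"] = survey["date"].dt.date
    cov = pd.DataFrame({
        "site_id": survey["site_id"],
        "geology": [geology[i % len(geology)] for i in range(n)],
        "tssc": np.round(r.uniform(0, 30, n), 2),
        "k_h": np.round(r.uniform(1, 40, n), 2),
        "s_y": np.round(r.uniform(0.02, 0.3, n), 3),
        "pgi_recharge": np.round(r.normal(300, 80, n), 1),
    })
    return survey, cov


@pytest.fixture
def small_dataset():
    survey, cov = make_survey()
    return Dataset(survey, cov)
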