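import numpy as np
import pandas as pd
import pytest

import longgwas as lg


@pytest.fixture(scope="session")
def ukb_small():
    """One UKB-like simulated dataset, 800 persons, ~50% singletons."""
    cfg = lg.make_scenario("ukb_like", n_persons=800)
    return lg.simulate_dataset(cfg, seed=20240501)


@pytest.fixture(scope="session")
def dense_panel():
    """Small fully-followed dataset (no singletons) for oracle comparisons."""
    cfg = lg.make_scenario("ukb_like", n_persons=300, singleton_fraction=0.0)
    return lg.simulate_dataset(cfg, seed=321)


@pytest.fixture()
def toy_table():
    """Hand-written 3-person trajectory table."""
    return pd.DataFrame({
        "person_id": ["a", "a", "a", "b", "b", "c"],
        "age": [50.0, 52.0, 55.0, 40.0, 49.0, 61.0],
        "value": [95.0, 93.0, 90.0, 110.0, 104.0, 80.0],
        "sex": [1, 1, 1, 0, 0, 1],
    })


def dense_loglik_reml(y, X, Z_blocks, codes, D, sigma2):
    """Dense multivariate-normal restricted log-likelihood (independent oracle)."""
    n_obs = len(y)
    V = np.zeros((n_obs, n_obs))
    for i, Zi in enumerate(Z_blocks):
        idx = np.flatnonzero(codes == i)
        V[np.ix_(idx, idx)] = Zi @ D @ Zi.T
    V += sigma2 * np.eye(n_obs)
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtVX)
    p = X.shape[1]
    return -0.5 * ((n_obs - p) * np.log(2 * np.pi) + ldV + ldX + r @ Vinv @ r)
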