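import numpy as np
import pandas as pd
import pytest

import riverpart as rp
from riverpart.sampling import TrainingSet


@pytest.fixture(scope="session")
def small_network():
    return rp.generate_network(150, n_outlets=3, seed=42)


@pytest.fixture(scope="session")
def epoch_pair(small_network):
    return rp.generate_predictors(small_network, rp.GeneratorConfig(), seed=7)


@pytest.fixture(scope="session")
def truth(small_network, epoch_pair):
    return rp.build_truth(epoch_pair, small_network, rp.GeneratorConfig(), seed=3)


def make_signal_train(n_rows=600, n_noise=3, beta=(2.5, -2.0), noise=0.0, seed=0):
    """Equal presence/background rows whose response depends on two predictors.

    ``noise=0`` gives deterministic labels (a separable problem); larger
    values blur the decision boundary.
    """
    rng = np.random.default_rng(seed)
    cols = {"sig_a": rng.normal(size=n_rows * 2), "sig_b": rng.normal(size=n_rows * 2)}
    for k in range(n_noise):
        cols[f"noise_{k}"] = rng.normal(size=n_rows * 2)
    X = pd.DataFrame(cols)
    score = beta[0] * X.sig_a + beta[1] * X.sig_b + noise * rng.normal(size=len(X))
    y = (score > np.median(score)).astype(np.int64)
    i1 = np.flatnonzero(y == 1)[:n_rows // 2]
    i0 = np.flatnonzero(y == 0)[:n_rows // 2]
    keep = np.concatenate([i1, i0])
    return TrainingSet(
        reach_ids=keep,
        response=y[keep],
        X=X.iloc[keep].reset_index(drop=True),
    )


@pytest.fixture(scope="session")
def signal_train():
    return make_signal_train(n_rows=400, seed=5)


@pytest.fixture(scope="session")
def signal_fit(signal_train):
    return rp.fit_brt(signal_train, tc=5, lr=0.1, n_trees=150, seed=9)
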