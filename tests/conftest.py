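import numpy as np
import pytest

from stopflow import data, simulate


@pytest.fixture(scope="session")
def campaign():
    """A labelled default 900-reaction synthetic campaign with ground truth."""
    dataset, truth = simulate.generate_library(simulate.SyntheticConfig(seed=42))
    return data.label_outcomes(dataset), truth


@pytest.fixture(scope="session")
def small_campaign():
    """A compact labelled campaign (3 acids x 3 amines x 4 agents x 3 conditions)."""
    from stopflow.design import build_condition_grid, ConditionPoint

    grid = build_condition_grid(
        3,
        ConditionPoint(120, 50, 1),
        ConditionPoint(360, 120, 2),
        ConditionPoint(600, 200, 3),
    )
    config = simulate.SyntheticConfig(n_acids=3, n_amines=3, seed=7, dropout_rate=0.05)
    dataset, truth = simulate.generate_library(config, grid=grid)
    return data.label_outcomes(dataset), truth


@pytest.fixture(scope="session")
def blobs():
    """Two well-separated Gaussian blobs in 2-D, n=200, balanced."""
    rng = np.random.default_rng(0)
    n = 100
    X0 = rng.normal([-2.0, -2.0], 0.5, size=(n, 2))
    X1 = rng.normal([2.0, 2.0], 0.5, size=(n, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    perm = rng.permutation(2 * n)
    return X[perm], y[perm]


TINY_SPACE = {
    "n_hidden_layers": [1],
    "units": [16],
    "alpha": [1e-4],
    "learning_rate": [3e-3],
    "epochs": [30],
    "batch_size": [32],
}


@pytest.fixture(scope="session")
def tiny_space():
    """One-point hyperparameter space for fast protocol runs."""
    return dict(TINY_SPACE)
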