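import numpy as np
import pytest

from grangernet import ExpressionMatrix, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_config():
    """A five-module network small enough for per-test simulation."""
    return SimulationConfig(
        module_repeats=5,
        perturbation_edges=20,
        total_nodes=80,
        seed=7,
    )


def make_var1_expression(B, T, sigma=0.0, seed=0, gene_ids=None):
    """Simulate an exact VAR(1) series x_t = B' x_{t-1} + noise.

    ``B`` is (n, n) with B[i, j] = effect of gene i on gene j, matching the
    package's coefficient convention.
    """
    rng = np.random.default_rng(seed)
    n = B.shape[0]
    x = np.empty((n, T))
    x[:, 0] = rng.standard_normal(n)
    for t in range(1, T):
        x[:, t] = B.T @ x[:, t - 1] + sigma * rng.standard_normal(n)
    ids = gene_ids or [f"g{i}" for i in range(n)]
    return ExpressionMatrix(ids, x)


@pytest.fixture
def var1_maker():
    return make_var1_expression
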