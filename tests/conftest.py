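import numpy as np
import pytest

from spred import (
    GrnConfig,
    SimParams,
    sample_grn,
    sample_interaction_params,
    sample_mr_rates,
    simulate_steady_state,
)


@pytest.fixture(scope="session")
def tiny_grn():
    """A fully parameterized 2-MR / 5-TF / 6-gene network."""
    cfg = GrnConfig(n_mr=2, n_tf=5, n_gene=6, d_mr_tf=1, d_tf_gene_range=(1, 3))
    return sample_interaction_params(sample_grn(cfg, 11), 12)


@pytest.fixture(scope="session")
def tiny_expression(tiny_grn):
    """Stochastic steady-state matrix for the tiny network (30 conditions)."""
    panel = sample_mr_rates(tiny_grn.n_mr, 30, seed=13)
    params = SimParams(burn_in=500, n_steps=100)
    return simulate_steady_state(tiny_grn, panel, params, seed=14)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
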