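import numpy as np
import pytest


def cp_tensor(U, V, W):
    """Rank-K tensor sum_k u_k o v_k o w_k, built entry by entry."""
    return np.einsum("rk,sk,tk->rst", U, V, W)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_planted():
    """Noiseless 30x30x12 tensor with 3 constant-signal planted modules."""
    from multifactv.synthetic_data import generate_planted_tensor

    return generate_planted_tensor(
        30, 30, 12, K=3, genes_per_module=6, conditions_per_module=6,
        interval_length=3, noise_density=0.0, seed=7,
        signal_low=0.8, signal_high=0.8,
    )
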