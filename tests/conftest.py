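import numpy as np
import pytest

from screenmix.null_model import NullFit, SkewTParams
from screenmix.simulate import FullSimConfig, simulate_full


@pytest.fixture(scope="session")
def small_screen():
    """A small fully simulated screen with truth labels (shared, read-only)."""
    cfg = FullSimConfig(
        n_genes_null=300,
        n_genes_pos=100,
        guides_per_gene=5,
        efficiency=0.9,
        n_controls=400,
        seed=1234,
    )
    return simulate_full(cfg)


@pytest.fixture(scope="session")
def std_normal_null():
    return NullFit(family="normal", params=(0.0, 1.0), log_likelihood=0.0, n=1000)


@pytest.fixture(scope="session")
def true_skew_t_null():
    return NullFit(
        family="skew_t",
        params=SkewTParams(0.0, 1.0, -1.5, 6.0),
        log_likelihood=0.0,
        n=1000,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
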