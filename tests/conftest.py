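import numpy as np
import pytest

import direqtl as dq


@pytest.fixture(scope="session")
def small_study():
    """A small annotation-driven study shared by slower integration tests."""
    cfg = dq.SimulationConfig(
        n_genes=60,
        n_samples=200,
        snps_per_gene=25,
        n_annotations=40,
        n_groups=(8, 5),
        n_causal=3,
        structured=True,
        seed=42,
    )
    return dq.simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
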