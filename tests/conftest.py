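import numpy as np
import pytest

from sdvar import synth


@pytest.fixture(scope="session")
def small_study():
    """A compact study with planted SDV genes, shared across tests."""
    cfg = synth.SynthConfig(
        n_genes=120, n_male=80, n_female=80, sdv_fraction=0.1,
        outlier_fraction=0.0, seed=101,
    )
    return synth.generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
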