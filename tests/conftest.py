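import numpy as np
import pytest

from nclabel import SyntheticConfig, make_benchmark


@pytest.fixture(scope="session")
def tiny_benchmark():
    """A small, quickly generated two-modality benchmark for pipeline tests."""
    cfg = SyntheticConfig(
        cells_per_type_ref=60,
        cells_per_type_target=80,
        n_genes=60,
        n_raw_features=600,
        seed=11,
    )
    return make_benchmark(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
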