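import numpy as np
import pytest

from jellynet import SimConfig, gen_annotation


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Scaled-down study configuration shared across tests."""
    return SimConfig(
        seed=11,
        n_mirna_genes=30,
        n_trna=40,
        n_other_nc=20,
        n_mrna=200,
        library_size_wj=50_000,
        library_size_rj=50_000,
        targets_per_mirna=(10, 30),
        expression_depth=200_000,
        timecourse_trends={"persistent_increase": 8, "transient_increase": 6,
                           "dip": 8, "persistent_fall": 4},
    )


@pytest.fixture(scope="session")
def small_catalog(small_cfg):
    return gen_annotation(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
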