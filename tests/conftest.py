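import numpy as np
import pytest
from hypothesis import settings

import graspsense as gs

settings.register_profile("det", derandomize=True, max_examples=50)
settings.load_profile("det")


@pytest.fixture(scope="session")
def cfg():
    return gs.default_config()


@pytest.fixture(scope="session")
def table2_rows():
    return gs.load_protocol(gs.default_protocol_path())


@pytest.fixture(scope="session")
def table2_dataset(cfg, table2_rows):
    """Full 80-closure acquisition, labeled, split 80/20 (seed 42)."""
    ds = gs.build_protocol_dataset(table2_rows, cfg, seed=42)
    return gs.split_dataset(ds, train_frac=0.8, seed=42)


@pytest.fixture(scope="session")
def default_model(table2_dataset):
    """One-vs-All classifier trained with the default configuration."""
    return gs.fit_ova(table2_dataset, gs.TrainConfig(seed=42))


@pytest.fixture(scope="session")
def test_dataset(cfg, table2_rows):
    """Held-out acquisition run with an independent seed."""
    return gs.build_protocol_dataset(table2_rows, cfg, seed=1042)
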