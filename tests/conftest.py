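import numpy as np
import pytest

from promtif.binfilter import build_dataset
from promtif.ordnet import PromoterTIFModel, TrainConfig
from promtif.simfacs import SortSimConfig, make_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """Small synthetic sorted library shared across tests (seeded)."""
    cfg = SortSimConfig(n_sequences=2500, seed=7)
    library, dataset, ortho_labels = make_fixture(cfg)
    return library, dataset, ortho_labels


@pytest.fixture(scope="session")
def small_results(small_fixture):
    """A quickly trained ordinal model on the small synthetic library."""
    _, dataset, _ = small_fixture
    model = PromoterTIFModel.from_dataset(
        dataset, train_config=TrainConfig(seed=3, max_epochs=15, patience=5))
    return model.fit()
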