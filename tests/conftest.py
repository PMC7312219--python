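import numpy as np
import pytest

from eegselect.evaluate import PortfolioSpec
from eegselect.features import build_feature_table
from eegselect.synth import SynthConfig, generate_epochs


@pytest.fixture(scope="session")
def fast_portfolio():
    """Reduced classifier grid for tests that loop over many subsets."""
    return PortfolioSpec(
        svm_kernels=("linear", "rbf"),
        knn_neighbors=(1, 3, 5),
        rf_depths=(3,),
        rf_n_estimators=25,
    )


@pytest.fixture(scope="session")
def planted_epochs():
    """8 channels, channel 1 informative at snr=3, 40+40 epochs."""
    cfg = SynthConfig(
        n_channels=8, informative_channels=frozenset({1}), n_per_class=40,
        snr=3.0, seed=7,
    )
    return generate_epochs(cfg)


@pytest.fixture(scope="session")
def planted_table_dwt(planted_epochs):
    return build_feature_table(planted_epochs, "dwt")


@pytest.fixture(scope="session")
def small_epochs():
    cfg = SynthConfig(
        n_channels=4, informative_channels=frozenset({1}), n_per_class=20,
        snr=3.0, seed=3,
    )
    return generate_epochs(cfg)


@pytest.fixture(scope="session")
def small_table_dwt(small_epochs):
    return build_feature_table(small_epochs, "dwt")


@pytest.fixture
def stub_score_cls():
    from helpers import StubScore

    return StubScore
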