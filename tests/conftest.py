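import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20150304)


@pytest.fixture
def four_instance_dataset():
    """Alternating labels at distinct scores: AUC 0.75 by hand enumeration."""
    from curveval import ScoredDataset

    return ScoredDataset.from_items([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])


@pytest.fixture
def tie_block_dataset():
    """One mixed tie block: upper/lower/average AUCs 1.0 / 0.75 / 0.875."""
    from curveval import ScoredDataset

    return ScoredDataset.from_items([0.9, 0.5, 0.5, 0.1], [1, 1, 0, 0])
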