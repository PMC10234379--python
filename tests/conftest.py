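import numpy as np
import pytest

import hetstat as hs

# the published plant example: a mother at h0 = 0.81 with 24 offspring,
# 15 fixed at 0, 3 fixed at 1, six intermediate
PLANT_VALUES = [0.0] * 15 + [1.0] * 3 + [0.91, 0.91, 0.92, 0.94, 0.95, 0.98]

# small synthetic example with visibly different MoM / ML / min-KS fits
SYNTH8 = [0.0, 0.0, 0.0, 0.0, 0.9, 0.9, 0.9, 0.9]


@pytest.fixture(scope="session")
def plant_sample() -> hs.HeteroplasmySample:
    return hs.HeteroplasmySample(PLANT_VALUES, reference_h=0.81)


@pytest.fixture(scope="session")
def synth8() -> hs.HeteroplasmySample:
    return hs.HeteroplasmySample(SYNTH8)


@pytest.fixture(scope="session")
def grouped_example() -> hs.GroupedSamples:
    """Two groups of two 2-observation sets with very different spreads."""
    return hs.GroupedSamples(
        [
            [hs.HeteroplasmySample([0.2, 0.4]), hs.HeteroplasmySample([0.6, 0.7])],
            [hs.HeteroplasmySample([0.1, 0.7]), hs.HeteroplasmySample([0.3, 1.0])],
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230323)
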