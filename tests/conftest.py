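import numpy as np
import pytest

from sbsp import BinaryFeatureMatrix, FeatureFrequencies, SBSPParams


@pytest.fixture
def toy_params():
    return SBSPParams(sigma=0.5, c=0.0, beta=1.0)


@pytest.fixture
def toy_matrix():
    # 3 samples, features f1..f4; f4 all-zero and dropped on construction
    arr = np.array(
        [
            [1, 1, 0, 0],
            [0, 1, 1, 0],
            [0, 1, 0, 0],
        ]
    )
    return BinaryFeatureMatrix.from_dense(arr, feature_ids=["f1", "f2", "f3", "f4"])


@pytest.fixture
def empty_stats():
    return FeatureFrequencies(n=0, k=0, m=[])


@pytest.fixture
def singleton_stats():
    return FeatureFrequencies(n=1, k=1, m=[1])
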