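import numpy as np
import pytest

from vowelage.synth import synth_feature_clusters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def complementary_frame():
    """Three streams, six age classes, each stream separating one age pair."""
    cmap = {"a": [7, 8], "e": [9, 10], "i": [11, 12]}
    return synth_feature_clusters(
        n_classes=6,
        n_per_class=24,
        dim=6,
        separation=5.0,
        seed=3,
        complementary_map=cmap,
        stream_offset=8.0,
    )


@pytest.fixture(scope="session")
def separable_frame():
    """One stream with well-separated age clusters (easy problem)."""
    return synth_feature_clusters(
        n_classes=6, n_per_class=18, dim=6, separation=10.0, seed=5
    )
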