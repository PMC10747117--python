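import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eegreduce.synth import SynthConfig, generate
from eegreduce.types import FeatureMatrix

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_synth_config() -> SynthConfig:
    """A quick condition: full montage, short segments, default effect."""
    return SynthConfig(
        train_seconds_per_class=30.0,
        test_seconds_per_class=15.0,
        record_seconds=15.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_split(small_synth_config):
    return generate(small_synth_config)


def blob_matrix(
    n: int = 200,
    p: int = 8,
    sep: float = 4.0,
    seed: int = 0,
    informative: int = 1,
) -> FeatureMatrix:
    """Two balanced Gaussian blobs separated along the first ``informative``
    columns; remaining columns are pure noise."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    rng.shuffle(y)
    X = rng.normal(size=(n, p))
    for j in range(informative):
        X[:, j] += sep * y
    names = tuple(f"Energy_ch{j}" for j in range(p))
    return FeatureMatrix(names, X, y)


@pytest.fixture
def blobs() -> FeatureMatrix:
    return blob_matrix(seed=3)
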