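import numpy as np
import pytest

from rankprune import Dataset, ConsensusConfig, GeneratorSpec, default_kernels, generate


@pytest.fixture(scope="session")
def blob_ds() -> Dataset:
    """Two well-separated Gaussian blobs (standardized separation 3)."""
    return generate(GeneratorSpec(n=200, p=5, p_informative=3, effect=3.0,
                                  seed=3))


@pytest.fixture(scope="session")
def blob_kernels(blob_ds):
    return default_kernels(blob_ds.numeric_matrix(), seed=3)


@pytest.fixture(scope="session")
def numeric_ds() -> Dataset:
    """Default numeric archetype: 300 x 50, 5 informative at effect 1.5."""
    return generate(GeneratorSpec(seed=1))


@pytest.fixture
def tiny_binary() -> Dataset:
    """Four points, one perfectly separating feature plus a dead one."""
    X = np.array([[1.0, 0.0], [2.0, 0.0], [-1.0, 0.0], [-2.0, 0.0]])
    y = np.array([1, 1, -1, -1])
    from rankprune import FeatureMeta

    return Dataset(X=X, y=y,
                   feature_meta=[FeatureMeta("a"), FeatureMeta("b")])


def admm_config(**overrides) -> ConsensusConfig:
    """Fixture configs give the consensus loop room to reach epsilon."""
    defaults = dict(P=1, epsilon=1e-4, max_iter=800, n_landmarks=1000,
                    landmark_seed=3)
    defaults.update(overrides)
    return ConsensusConfig(**defaults)
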