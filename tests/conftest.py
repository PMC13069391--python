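import numpy as np
import pytest
from hypothesis import settings

import morphodelim as md

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture
def tiny_dataset() -> md.MorphoDataset:
    """Two OTUs, two characters, hand-checkable values."""
    return md.MorphoDataset(
        specimen_ids=[str(i) for i in range(1, 7)],
        otu_labels=np.array(["A", "A", "A", "B", "B", "B"], dtype=object),
        body_size=np.array([50.0, 55.0, 60.0, 40.0, 44.0, 48.0]),
        characters=np.array([[2.0, 10.0], [3.0, 11.0], [2.5, 12.0],
                             [4.0, 5.0], [5.0, 6.0], [6.0, 5.5]]),
        character_names=["HL", "TL"],
    )


@pytest.fixture(scope="session")
def two_cluster_data() -> tuple[np.ndarray, np.ndarray]:
    """Two well-separated Gaussian clusters with distinct covariances."""
    rng = np.random.default_rng(42)
    a = rng.multivariate_normal([0, 0, 0], np.diag([1.0, 2.0, 0.5]), 120)
    b = rng.multivariate_normal([8, 7, 6], [[2.0, 0.5, 0.0], [0.5, 1.0, 0.3], [0.0, 0.3, 1.0]], 100)
    X = np.vstack([a, b])
    labels = np.array(["A"] * 120 + ["B"] * 100, dtype=object)
    return X, labels


@pytest.fixture(scope="session")
def overlapping_data() -> np.ndarray:
    """Two overlapping clusters, so EM genuinely iterates."""
    rng = np.random.default_rng(3)
    return np.vstack([
        rng.multivariate_normal([0, 0], [[1.0, 0.3], [0.3, 1.0]], 80),
        rng.multivariate_normal([2.0, 1.5], [[0.5, -0.2], [-0.2, 0.8]], 70),
    ])


@pytest.fixture(scope="session")
def mimic() -> md.MorphoDataset:
    return md.desmognathus_mimic(seed=11)


@pytest.fixture(scope="session")
def mimic_corrected(mimic) -> np.ndarray:
    return md.corrected_dataset(mimic, "pooled").matrix()
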