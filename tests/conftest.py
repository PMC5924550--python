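import numpy as np
import pytest

from cnvsift.dataset import CopyNumberDataset


@pytest.fixture
def tiny_dataset() -> CopyNumberDataset:
    """3 probes x 4 samples, unlabeled."""
    rng = np.random.default_rng(42)
    return CopyNumberDataset(
        probe_ids=["p1", "p2", "p3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=rng.normal(0, 0.05, size=(3, 4)),
    )


@pytest.fixture
def labeled_dataset(tiny_dataset) -> CopyNumberDataset:
    from cnvsift.dataset import attach_labels

    return attach_labels(
        tiny_dataset, {"s1": "case", "s2": "CASE", "s3": "control", "s4": "0"}
    )


@pytest.fixture
def separable_xy():
    """200 samples where one feature cleanly thresholds the label."""
    rng = np.random.default_rng(7)
    n = 200
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 0.05, size=(n, 5))
    X[:, 2] += np.where(y == 1, 0.5, 0.0)
    perm = rng.permutation(n)
    return X[perm], y[perm]
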