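import warnings

import numpy as np
import pytest

from stfl.synthetic import (
    ConfidenceStreamSpec,
    SyntheticSpec,
    generate_image_dataset,
)


@pytest.fixture(autouse=True)
def _silence_metric_warnings():
    # zero-denominator metric warnings are expected on tiny evaluation sets
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*zero denominator.*")
        warnings.filterwarnings("ignore", message=".*excluded from macro.*")
        yield


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny 3-class imbalanced image dataset shared across tests."""
    spec = SyntheticSpec(
        n_classes=3,
        class_proportions=np.array([0.6, 0.3, 0.1]),
        n_labeled=60,
        n_unlabeled=120,
        n_test=60,
        seed=7,
    )
    return generate_image_dataset(spec)


@pytest.fixture()
def two_class_stream_spec():
    """The imbalanced 2-class stream used for selection-balance checks."""
    return ConfidenceStreamSpec(
        n_classes=2,
        batch_size=64,
        n_batches=200,
        per_class_confidence_params=((30.0, 2.0), (8.0, 4.0)),
        class_priors=np.array([0.9, 0.1]),
        corruption_rate=0.0,
        seed=11,
    )


def rowstoch(rng, n, c):
    """Random row-stochastic matrix."""
    x = rng.random((n, c)) + 1e-3
    return x / x.sum(axis=1, keepdims=True)
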