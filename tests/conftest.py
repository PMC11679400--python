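import numpy as np
import pytest

from dasleep import (
    DomainConfig,
    EpochSeries,
    HypnogramConfig,
    sample_counts,
    sample_hypnogram,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def night():
    """One labeled synthetic night under the default source domain."""
    hyp = sample_hypnogram(HypnogramConfig(), seed=11)
    return sample_counts(hyp, DomainConfig(), seed=12, subject_id="n0")


@pytest.fixture()
def tiny_series():
    """A short hand-checkable record (30-s epochs)."""
    counts = np.array([0.0, 0, 3, 120, 45, 0, 0, 2, 1, 0, 0, 0])
    labels = np.array([1, 1, 1, 0, 0, 1, 1, 1, 1, 1, 1, 1])
    return EpochSeries("tiny", "source", counts, labels)
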