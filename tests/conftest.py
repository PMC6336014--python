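import numpy as np
import pytest

from germfda.curve_model import GerminationRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def logistic_record(rng, accession="ACC001", treatment="T25_15", seeds=25,
                    midpoint=8.0, scale=2.0, final=1.0):
    """Noisy logistic-shaped cumulative count series over days 1..28."""
    days = np.arange(1, 29, dtype=float)
    mean = final * seeds / (1 + np.exp(-(days - midpoint) / scale))
    noisy = np.clip(mean + rng.normal(0, 0.7, days.size), 0, seeds)
    counts = np.round(np.maximum.accumulate(noisy))
    return GerminationRecord(accession, treatment, 1, seeds, days, counts)


@pytest.fixture
def logistic_rec(rng):
    return logistic_record(rng)
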