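import numpy as np
import pytest

from topogait.signal import TimeSeries
from topogait.synthetic import CohortSpec, generate_cohort


def random_barcode(rng, max_finite=5, with_infinite=True, scale=5.0):
    """A random barcode as a list of (birth, death) pairs."""
    import math

    m = int(rng.integers(0, max_finite + 1))
    births = rng.uniform(-scale, scale, size=m)
    lengths = rng.uniform(1e-3, scale, size=m)
    bars = [(float(b), float(b + l)) for b, l in zip(births, lengths)]
    if with_infinite:
        bars.append((float(rng.uniform(-scale, scale)), math.inf))
    return bars


def random_signal(rng, n=60, smooth=False):
    """A random finite signal; smooth variants via cumulative sums."""
    if smooth:
        return np.cumsum(rng.standard_normal(n)) / np.sqrt(n)
    return rng.standard_normal(n)


@pytest.fixture(scope="session")
def two_group_cohort():
    """Planted severity separation: healthy vs patient, single session."""
    spec = CohortSpec(n_hs=4, n_ms=4, sessions=("M0",), trials_per_session=2,
                      seed=7)
    return generate_cohort(spec), spec


@pytest.fixture
def sinusoid():
    t = np.arange(0, 5.0, 0.01)
    return TimeSeries(values=np.sin(2 * np.pi * t), sampling_rate=100.0,
                      trial_id="sin")
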