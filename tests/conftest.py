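import numpy as np
import pytest

from smoothcast.lagspace import RegressorSet
from smoothcast.series import TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_series():
    return TimeSeries([1.0, 4.0, 1.0, 4.0, 1.0])


@pytest.fixture
def linear_regressors(rng):
    """Noiseless targets exactly linear in two regressors."""
    Z = rng.uniform(0.0, 1.0, size=(200, 2))
    y = 0.3 * Z[:, 0] + 0.5 * Z[:, 1] + 0.1
    return RegressorSet(Z, y, np.arange(3, 203))


def make_regressors(Z, y, first_t=None):
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    start = Z.shape[1] + 1 if first_t is None else first_t
    return RegressorSet(Z, y, np.arange(start, start + y.size))
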