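import numpy as np
import pandas as pd
import pytest

from igradient.core import EpochSeries
from igradient.simulate import SimConfig

T0 = pd.Timestamp("2024-01-01 08:00:00")


def make_series(values, units="counts", epoch_length=15.0, wear=None,
                participant="P00", device="dev", start=T0):
    values = np.asarray(values, dtype=float)
    if units == "counts":
        values = np.round(values)
    return EpochSeries(participant, device, start, values, epoch_length,
                       wear=wear, units=units)


@pytest.fixture
def cfg():
    return SimConfig(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
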