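import numpy as np
import pandas as pd
import pytest

from actiprofile.epochs import EpochSeries
from actiprofile.wear import DayRecord, day_validity

EPD_5S = 86_400 // 5


def make_day(values, epoch_len_s=5, date="2024-01-01", wear=None) -> DayRecord:
    """Wrap raw epoch values into a validated one-day record."""
    values = np.asarray(values, dtype=float)
    series = EpochSeries(pd.Timestamp(date), epoch_len_s, values, wear)
    return day_validity(DayRecord(date=series.start.date(), epochs=series))


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def random_day(rng):
    """A full 5-s-epoch day of heavy-tailed random ENMO values."""
    return make_day(rng.lognormal(mean=2.0, sigma=1.5, size=EPD_5S))
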