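import numpy as np
import pytest

from rssistep import ChannelModel, PathLossSeries


@pytest.fixture
def model():
    """Default 2.4 GHz channel with the 10 dB correction factor."""
    return ChannelModel()


def make_series(values) -> PathLossSeries:
    """A clean PathLossSeries holding exactly the given dB values."""
    values = np.asarray(values, dtype=float)
    return PathLossSeries(values_db=values, n_total=values.size)


@pytest.fixture
def series_factory():
    return make_series
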