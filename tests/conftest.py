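import datetime as dt

import numpy as np
import pandas as pd
import pytest

from dtrheat import DailySeries, DistrictMeta
from dtrheat.synthetic import DistrictRegime


def make_series(district="D1", start="2015-01-01", tmax=(), tmin=()):
    """Small hand-built series helper used across the unit tests."""
    return DailySeries.from_arrays(district, start, np.asarray(tmax, float),
                                   np.asarray(tmin, float))


@pytest.fixture
def meta_d1():
    return DistrictMeta("D1", "TestProv", mmt=20.0, centroid_lat=-29.0,
                        centroid_lon=25.0, coastal=False)


@pytest.fixture
def flat_regime():
    """Noiseless, season-free regime: DTR constant at 10 degC, below threshold."""
    return DistrictRegime(
        district_id="FLAT", coastal=False, tmax_mean_annual=26.0,
        seasonal_amplitude_tmax=5.0, seasonal_amplitude_tmin=5.0,
        dtr_base=10.0, noise_sd=0.0, mmt=18.0,
    )
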