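import datetime as dt

import numpy as np
import pandas as pd
import pytest

COLLECTION = "2015-03-15"


def make_daily(start="2009-01-01", end="2015-03-14", tmean=20.0, precip=1.0,
               rh=60.0, **extra):
    """Flat daily series covering 5 years + lead-in before COLLECTION."""
    dates = pd.date_range(start, end, freq="D")
    df = pd.DataFrame({"date": dates, "tmean_c": tmean, "precip_mm": precip,
                       "rh_pct": rh})
    for col, val in extra.items():
        df[col] = val
    return df


@pytest.fixture
def flat_series():
    return make_daily()


@pytest.fixture
def collection_date():
    return COLLECTION


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
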