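import numpy as np
import pandas as pd
import pytest

from ppafire.grid import Grid, GriddedField


def season_dates(years, months=(3, 10)):
    """Daily date index covering the season window of each given year."""
    parts = []
    for y in years:
        last = pd.Timestamp(y, months[1], 1) + pd.offsets.MonthEnd(0)
        parts.append(pd.date_range(pd.Timestamp(y, months[0], 1), last, freq="D"))
    return parts[0].append(parts[1:])


def make_field(values, lat0=40.0, lon0=0.0, years=(2001, 2002), months=(3, 10), name="z500"):
    """GriddedField from a (time, nlat, nlon) array with a simple grid."""
    values = np.asarray(values, dtype=float)
    dates = season_dates(years, months)
    assert len(dates) == values.shape[0], (len(dates), values.shape)
    grid = Grid(lat=lat0 + np.arange(values.shape[1]), lon=lon0 + np.arange(values.shape[2]))
    return GriddedField(grid=grid, dates=dates, values=values, name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return Grid(lat=40.0 + np.arange(5), lon=np.arange(6, dtype=float))
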