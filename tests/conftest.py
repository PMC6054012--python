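import datetime as dt

import numpy as np
import pandas as pd
import pytest

from respdiv.weather import WeatherSeries, segment_season
from respdiv.variables import CutSchedule, EnvironmentUnit


def make_series(
    site_id: str,
    start: dt.date,
    tmean,
    tmin=None,
    tmax=None,
    precip=None,
) -> WeatherSeries:
    """WeatherSeries from plain arrays; tmin/tmax default to tmean ∓ 5."""
    tmean = np.asarray(tmean, float)
    n = len(tmean)
    idx = pd.date_range(start, periods=n, freq="D")
    frame = pd.DataFrame(
        {
            "tmean": tmean,
            "tmin": tmean - 5.0 if tmin is None else np.asarray(tmin, float),
            "tmax": tmean + 5.0 if tmax is None else np.asarray(tmax, float),
            "precip": np.zeros(n) if precip is None else np.asarray(precip, float),
        },
        index=idx,
    )
    return WeatherSeries(site_id, frame)


def _override(series_start: dt.date, arr, day: dt.date, value: float) -> None:
    arr[(day - series_start).days] = value


@pytest.fixture(scope="session")
def toy_season():
    """A fully hand-constructed site-season with known values of all 14
    agroclimatic variables.

    Construction (season year 2010, series 2009-08-01..2010-09-15):

    * tmean 5 °C through 10 Sep (balance stays 0), then 3 °C → the FH
      starts 10 Sep; a two-day frost (tmin −12) on 18–19 Oct ends it.
      FH = [2009-09-10, 2009-10-19], 40 days; cold sum 39 × 2 = 78;
      rain 1.46 mm on each FH day → total 58.4 mm.
    * winter tmean −2 °C, ten days of +2 °C (1–10 Dec), five cold-stress
      days with tmin −16 (10–14 Jan); late April ramp: 21–25 Apr at 4 °C,
      then 10 °C from 26 Apr → GP starts 30 Apr, WP = [2009-10-20,
      2010-04-29], 192 days; warm sum 10×2 + 5×4 + 4×10 = 80.
    * GP runs to the last cut 25 Aug (118 days), tmean 10 °C except
      17.3 °C on 16–22 Jun (the 7 days after the 15 Jun first cut).
    """
    start = dt.date(2009, 8, 1)
    end = dt.date(2010, 9, 15)
    n = (end - start).days + 1
    d = lambda y, m, dd: dt.date(y, m, dd)  # noqa: E731

    tmean = np.full(n, np.nan)

    def fill(a, b, value, arr=tmean):
        arr[(a - start).days : (b - start).days + 1] = value

    fill(d(2009, 8, 1), d(2009, 9, 10), 5.0)
    fill(d(2009, 9, 11), d(2009, 10, 19), 3.0)
    fill(d(2009, 10, 20), d(2010, 4, 20), -2.0)
    fill(d(2009, 12, 1), d(2009, 12, 10), 2.0)
    fill(d(2010, 4, 21), d(2010, 4, 25), 4.0)
    fill(d(2010, 4, 26), d(2010, 9, 15), 10.0)
    fill(d(2010, 6, 16), d(2010, 6, 22), 17.3)
    assert not np.isnan(tmean).any()

    tmin = tmean - 5.0
    for day in (d(2009, 10, 18), d(2009, 10, 19)):
        _override(start, tmin, day, -12.0)
    for k in range(10, 15):  # 10–14 Jan
        _override(start, tmin, d(2010, 1, k), -16.0)

    tmax = tmean + 5.0
    for k in (5, 6, 7):
        _override(start, tmax, d(2010, 5, k), 26.0)
    _override(start, tmax, d(2010, 6, 25), 25.0)
    _override(start, tmax, d(2010, 7, 5), 25.0)
    _override(start, tmax, d(2010, 7, 25), 28.0)
    _override(start, tmax, d(2010, 8, 1), 29.0)

    precip = np.zeros(n)
    fill(d(2009, 9, 10), d(2009, 10, 19), 1.46, precip)
    fill(d(2010, 5, 10), d(2010, 5, 19), 2.0, precip)
    fill(d(2010, 6, 17), d(2010, 6, 21), 0.9, precip)
    _override(start, precip, d(2010, 7, 10), 1.5)

    series = make_series("toy", start, tmean, tmin, tmax, precip)
    cuts = CutSchedule(cut1=d(2010, 6, 15), cut2=d(2010, 7, 20),
                       last_cut=d(2010, 8, 25))
    seg = segment_season(series, 2010, cuts.last_cut)
    unit = EnvironmentUnit("toy", "e1", 2010, seg, cuts)

    expected = {
        "FH_LENGTH": 40.0,
        "FH_COLD5": 78.0,
        "FH_RAIN": 1.46,
        "WP_WARM0_RATE": 80.0 / 192.0,
        "WP_STRESS15": 5.0,
        "GP_TSUM5": 641.1,
        "GP_TSUM_RATE": 641.1 / 118.0,
        "GP_HOT25_CUT1": 3.0,
        "GP_HOT25_CUT2": 2.0,
        "GP_HOT28": 2.0,
        "GP_POSTCUT_TSUM7": 121.1,
        "GP_RAIN_CUT1": 20.0,
        "GP_RAIN_CUT2": 6.0,
        "GP_POSTCUT_RAIN14": 4.5,
    }
    return series, unit, expected
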