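import datetime as dt

import numpy as np
import pandas as pd
import pytest

from respdiv.weather import (
    FLAG_FH_DEGENERATE,
    FLAG_FH_NO_FROST_CAPPED,
    FLAG_INCOMPLETE_WEATHER,
    FLAG_NO_GP_SPELL,
    IncompleteWeatherError,
    PeriodSpan,
    WeatherSeries,
    find_fall_hardening,
    find_growth_period_start,
    segment_season,
)
from respdiv.synth import WeatherGenConfig, generate_weather

from _oracles import fh_oracle, gp_oracle
from conftest import make_series


def _autumn_series(tmean_by_span, frost_days=(), start=dt.date(2004, 8, 1),
                   end=dt.date(2005, 8, 31)):
    n = (end - start).days + 1
    tmean = np.full(n, np.nan)
    for (a, b), v in tmean_by_span:
        tmean[(a - start).days:(b - start).days + 1] = v
    assert not np.isnan(tmean).any()
    tmin = tmean - 5.0
    for day in frost_days:
        tmin[(day - start).days] = -12.0
    return make_series("s", start, tmean, tmin)


class TestFallHardening:
    def test_balance_and_single_frost_day(self):
        # tmean 5 °C to 10 Aug (balance 0), then 2 °C; lone frost day 1 Oct
        series = _autumn_series(
            [((dt.date(2004, 8, 1), dt.date(2004, 8, 10)), 5.0),
             ((dt.date(2004, 8, 11), dt.date(2005, 8, 31)), 2.0)],
            frost_days=[dt.date(2004, 10, 1)],
        )
        span, flags = find_fall_hardening(series, 2005)
        assert span == PeriodSpan(dt.date(2004, 8, 10), dt.date(2004, 10, 1))
        assert span.length_days == 53
        assert not flags

    def test_warm_frost_free_series_is_absent(self):
        series = _autumn_series(
            [((dt.date(2004, 8, 1), dt.date(2005, 8, 31)), 10.0)]
        )
        span, flags = find_fall_hardening(series, 2005)
        assert span is None
        assert flags == {FLAG_FH_NO_FROST_CAPPED, FLAG_FH_DEGENERATE}

    def test_cold_august_starts_on_first_day(self):
        # balance positive from day one -> start 1 August by convention
        series = _autumn_series(
            [((dt.date(2004, 8, 1), dt.date(2005, 8, 31)), 2.0)],
            frost_days=[dt.date(2004, 11, 5)],
        )
        span, flags = find_fall_hardening(series, 2005)
        assert span.start == dt.date(2004, 8, 1)
        assert span.end == dt.date(2004, 11, 5)

    def test_multiday_frost_spell_ends_on_last_day(self):
        series = _autumn_series(
            [((dt.date(2004, 8, 1), dt.date(2004, 8, 10)), 5.0),
             ((dt.date(2004, 8, 11), dt.date(2005, 8, 31)), 2.0)],
            frost_days=[dt.date(2004, 10, 1), dt.date(2004, 10, 2),
                        dt.date(2004, 10, 3), dt.date(2004, 10, 20)],
        )
        span, _ = find_fall_hardening(series, 2005)
        assert span.end == dt.date(2004, 10, 3)

    def test_missing_window_raises(self):
        series = _autumn_series(
            [((dt.date(2004, 8, 1), dt.date(2005, 8, 31)), 2.0)],
        )
        with pytest.raises(IncompleteWeatherError):
            find_fall_hardening(series, 2006)


class TestGrowthPeriodStart:
    @staticmethod
    def _spring(tmean_fn):
        start = dt.date(2005, 1, 1)
        n = (dt.date(2005, 7, 31) - start).days + 1
        tmean = np.array([tmean_fn(start + dt.timedelta(days=i)) for i in range(n)])
        return make_series("s", start, tmean)

    def test_fifth_day_of_first_spell(self):
        series = self._spring(
            lambda d: 6.0 if d >= dt.date(2005, 4, 26) else 4.0
        )
        day, flags = find_growth_period_start(series, 2005)
        assert day == dt.date(2005, 4, 30)
        assert not flags

    def test_broken_spell_restarts_count(self):
        # from 1 Apr: 6,6,6,6,4,6,6,6,6,6 -> spell broken on 5 Apr, GP 10 Apr
        def fn(d):
            if d < dt.date(2005, 4, 1):
                return 3.0
            offset = (d - dt.date(2005, 4, 1)).days
            if offset == 4:
                return 4.0
            return 6.0

        series = self._spring(fn)
        day, _ = find_growth_period_start(series, 2005)
        assert day == dt.date(2005, 4, 10)

    def test_no_spell_flagged(self):
        series = self._spring(lambda d: 4.0)
        day, flags = find_growth_period_start(series, 2005)
        assert day is None
        assert flags == {FLAG_NO_GP_SPELL}


class TestSegmentSeason:
    def _full_series(self):
        start = dt.date(2004, 8, 1)
        end = dt.date(2005, 9, 30)
        n = (end - start).days + 1
        tmean = np.full(n, 2.0)

        def fill(a, b, v):
            tmean[(a - start).days:(b - start).days + 1] = v

        fill(dt.date(2004, 8, 1), dt.date(2004, 9, 1), 5.0)   # balance 0 to 1 Sep
        fill(dt.date(2004, 10, 16), dt.date(2005, 4, 15), -3.0)
        fill(dt.date(2005, 4, 16), dt.date(2005, 9, 30), 8.0)  # spell from 16 Apr
        tmin = tmean - 5.0
        for day in (dt.date(2004, 10, 10), dt.date(2004, 10, 15)):
            tmin[(day - start).days] = -11.0
        return make_series("s", start, tmean, tmin)

    def test_adjacency_and_gp_end(self):
        series = self._full_series()
        seg = segment_season(series, 2005, dt.date(2005, 8, 30))
        assert seg.fh.start == dt.date(2004, 9, 1)
        assert seg.fh.end == dt.date(2004, 10, 10)
        assert seg.wp == PeriodSpan(dt.date(2004, 10, 11), dt.date(2005, 4, 19))
        assert seg.gp == PeriodSpan(dt.date(2005, 4, 20), dt.date(2005, 8, 30))

    def test_harvest_before_gp_start_raises(self):
        series = self._full_series()
        with pytest.raises(ValueError, match="precedes GP start"):
            segment_season(series, 2005, dt.date(2005, 3, 1))

    def test_absent_fh_keeps_gp(self):
        start = dt.date(2004, 8, 1)
        end = dt.date(2005, 9, 30)
        n = (end - start).days + 1
        series = make_series("s", start, np.full(n, 10.0))
        seg = segment_season(series, 2005, dt.date(2005, 8, 30))
        assert seg.fh is None and seg.wp is None
        assert seg.gp is not None
        assert FLAG_FH_DEGENERATE in seg.flags

    def test_missing_day_flags_incomplete(self):
        series = self._full_series()
        frame = series.frame.drop(pd.Timestamp("2005-02-10"))
        gappy = WeatherSeries("s", frame)
        assert dt.date(2005, 2, 10) in gappy.missing_days
        seg = segment_season(gappy, 2005, dt.date(2005, 8, 30))
        assert seg.flags == {FLAG_INCOMPLETE_WEATHER}
        assert seg.fh is None and seg.gp is None

    def test_determinism(self):
        series = self._full_series()
        a = segment_season(series, 2005, dt.date(2005, 8, 30))
        b = segment_season(series, 2005, dt.date(2005, 8, 30))
        assert (a.fh, a.wp, a.gp, a.flags) == (b.fh, b.wp, b.gp, b.flags)


class TestSeriesValidation:
    def test_duplicate_days_rejected(self):
        idx = pd.to_datetime(["2005-01-01", "2005-01-01"])
        frame = pd.DataFrame(
            {"tmean": [0.0, 0.0], "tmin": [-1.0, -1.0], "tmax": [1.0, 1.0],
             "precip": [0.0, 0.0]}, index=idx,
        )
        with pytest.raises(ValueError, match="duplicate"):
            WeatherSeries("s", frame)

    def test_temperature_ordering_enforced(self):
        idx = pd.date_range("2005-01-01", periods=2, freq="D")
        frame = pd.DataFrame(
            {"tmean": [0.0, 0.0], "tmin": [1.0, -1.0], "tmax": [2.0, 1.0],
             "precip": [0.0, 0.0]}, index=idx,
        )
        with pytest.raises(ValueError, match="tmin <= tmean"):
            WeatherSeries("s", frame)


class TestOracleEquivalence:
    def test_synthetic_years_match_brute_force(self):
        """Engine spans equal a literal day-scan oracle on seeded years."""
        n_agree = 0
        for seed in range(50):
            cfg = WeatherGenConfig(seed=seed)
            series = generate_weather(cfg, f"w{seed}", [2004, 2005])
            span, flags = find_fall_hardening(series, 2005)
            o_start, o_end = fh_oracle(series, 2005)
            if span is None:
                assert o_start is None
            else:
                assert (span.start, span.end) == (o_start, o_end)
            gp, _ = find_growth_period_start(series, 2005)
            assert gp == gp_oracle(series, 2005)
            n_agree += 1
        assert n_agree == 50


class TestProperties:
    def test_fh_start_monotone_under_cooling(self):
        """Cooling the whole series never delays the FH start."""
        for seed in range(12):
            series = generate_weather(WeatherGenConfig(seed=seed), "m", [2004, 2005])
            base, _ = find_fall_hardening(series, 2005)
            for delta in (0.5, 2.0, 5.0):
                frame = series.frame.copy()
                for col in ("tmean", "tmin", "tmax"):
                    frame[col] = frame[col] - delta
                cooled, _ = find_fall_hardening(WeatherSeries("m", frame), 2005)
                if base is not None and cooled is not None:
                    assert cooled.start <= base.start

    def test_segmentation_invariants_on_batch(self):
        one = dt.timedelta(days=1)
        n_checked = 0
        for seed in range(50):
            series = generate_weather(WeatherGenConfig(seed=seed), "b", [2004, 2005])
            seg = segment_season(series, 2005, dt.date(2005, 8, 30))
            if seg.fh and seg.wp:
                assert seg.wp.start == seg.fh.end + one
            if seg.wp and seg.gp:
                assert seg.wp.end == seg.gp.start - one
            spans = [s for s in (seg.fh, seg.wp, seg.gp) if s]
            for a, b in zip(spans, spans[1:]):
                assert a.end < b.start
            n_checked += 1
        assert n_checked == 50
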