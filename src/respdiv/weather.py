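"""Phenological segmentation of daily weather series.

A harvest season at a northern site is split into three periods that
drive overwintering forage performance:

* **Fall hardening (FH)** — starts on the last day after 1 August on
  which the running balance of cold degree-days below 5 °C minus warm
  degree-days above 5 °C is still at or below zero, and ends on the last
  day of the first spell of daily minima at or below −10 °C.
* **Winter period (WP)** — from the day after FH ends to the day before
  the growth period starts.
* **Growth period (GP)** — from the fifth day of the first run of five
  consecutive days with daily mean temperature above 5 °C, to the last
  harvest of the season.

All dates are whole calendar days and all spans are inclusive on both
ends.  The FH of season ``y`` lies in the autumn of ``y − 1``; the WP
bridges the calendar-year boundary.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FLAG_FH_NO_FROST_CAPPED",
    "FLAG_FH_DEGENERATE",
    "FLAG_NO_GP_SPELL",
    "FLAG_INCOMPLETE_WEATHER",
    "IncompleteWeatherError",
    "PeriodSpan",
    "SeasonSegmentation",
    "WeatherSeries",
    "find_fall_hardening",
    "find_growth_period_start",
    "segment_season",
    "read_weather_csv",
    "write_segmentation_csv",
]

# Rule constants (°C).
HARDENING_BASE = 5.0          # degree-day base for the FH balance
FH_FROST_THRESHOLD = -10.0    # daily minimum that terminates hardening
GP_SPELL_THRESHOLD = 5.0      # daily mean that counts toward the warm spell
GP_SPELL_DAYS = 5
FH_SEARCH_END = (4, 30)       # month, day: horizon for the FH search (30 April)

FLAG_FH_NO_FROST_CAPPED = "fh_no_frost_capped"
FLAG_FH_DEGENERATE = "fh_degenerate"
FLAG_NO_GP_SPELL = "no_gp_spell"
FLAG_INCOMPLETE_WEATHER = "incomplete_weather"

#: numerical slack for "the balance was 0": daily contributions are exact
#: decimals but long cumulative sums are not.
_BALANCE_TOL = 1e-9


class IncompleteWeatherError(ValueError):
    """The weather series does not cover a required date range."""


@dataclass(frozen=True, order=True)
class PeriodSpan:
    """An inclusive span of calendar days."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"span start {self.start} after end {self.end}")

    @property
    def length_days(self) -> int:
        return (self.end - self.start).days + 1

    def contains(self, day: dt.date) -> bool:
        return self.start <= day <= self.end


@dataclass
class SeasonSegmentation:
    """FH/WP/GP spans for one site-season, with validity flags.

    Any span may be absent (``None``); the flags say why.  When present
    together the spans are pairwise disjoint, ordered FH < WP < GP, and
    adjacent: ``wp.start == fh.end + 1`` and ``wp.end == gp.start − 1``.
    """

    site_id: str
    season_year: int
    fh: PeriodSpan | None = None
    wp: PeriodSpan | None = None
    gp: PeriodSpan | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        one_day = dt.timedelta(days=1)
        if self.fh is not None and self.wp is not None:
            if self.wp.start != self.fh.end + one_day:
                raise ValueError("WP must start the day after FH ends")
        if self.wp is not None and self.gp is not None:
            if self.wp.end != self.gp.start - one_day:
                raise ValueError("WP must end the day before GP starts")
        spans = [s for s in (self.fh, self.wp, self.gp) if s is not None]
        for a, b in zip(spans, spans[1:]):
            if a.end >= b.start:
                raise ValueError("periods must be disjoint and ordered")


class WeatherSeries:
    """Ordered daily weather records for one site.

    Wraps a DataFrame indexed by calendar day with columns ``tmean``,
    ``tmin``, ``tmax``, ``precip``.  Dates must be strictly increasing;
    days missing from the covered range are recorded in
    :attr:`missing_days` rather than silently interpolated.
    """

    def __init__(self, site_id: str, frame: pd.DataFrame) -> None:
        required = {"tmean", "tmin", "tmax", "precip"}
        missing_cols = required - set(frame.columns)
        if missing_cols:
            raise ValueError(f"weather frame lacks columns {sorted(missing_cols)}")
        idx = pd.DatetimeIndex(frame.index)
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique()
            raise ValueError(f"duplicate site-days for {site_id}: {list(dups.date)[:5]}")
        frame = frame.iloc[idx.argsort()].copy()
        frame.index = pd.DatetimeIndex(frame.index).normalize()
        bad = frame[(frame["tmin"] > frame["tmean"]) | (frame["tmean"] > frame["tmax"])]
        if len(bad):
            raise ValueError(
                f"tmin <= tmean <= tmax violated for {site_id} on {list(bad.index.date)[:5]}"
            )
        if (frame["precip"] < 0).any():
            raise ValueError(f"negative precipitation for {site_id}")
        self.site_id = site_id
        self._frame = frame
        full = pd.date_range(frame.index[0], frame.index[-1], freq="D")
        self.missing_days: frozenset[dt.date] = frozenset(
            full.difference(frame.index).date
        )

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def first_day(self) -> dt.date:
        return self._frame.index[0].date()

    @property
    def last_day(self) -> dt.date:
        return self._frame.index[-1].date()

    def covers(self, start: dt.date, end: dt.date) -> bool:
        """True when every day in [start, end] has a record."""
        if start < self.first_day or end > self.last_day:
            return False
        return not any(start <= d <= end for d in self.missing_days)

    def window(self, start: dt.date, end: dt.date) -> pd.DataFrame:
        """Records for [start, end]; raises if any day is missing."""
        if not self.covers(start, end):
            raise IncompleteWeatherError(
                f"site {self.site_id}: weather does not cover "
                f"{start.isoformat()}..{end.isoformat()} "
                f"(have {self.first_day.isoformat()}..{self.last_day.isoformat()}, "
                f"{len(self.missing_days)} missing days)"
            )
        return self._frame.loc[pd.Timestamp(start) : pd.Timestamp(end)]


def _run_bounds(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/end index pairs (inclusive) of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def find_fall_hardening(
    series: WeatherSeries, season_year: int
) -> tuple[PeriodSpan | None, frozenset[str]]:
    """Locate the fall-hardening span preceding ``season_year``.

    Searches 1 August of ``season_year − 1`` through the following
    30 April.  The start is the last day on which the cumulative balance
    ``S(d) = Σ [max(0, 5 − tmean) − max(0, tmean − 5)]`` is ≤ 0 (1 August
    when the balance is positive from the first day); the end is the
    last day of the first frost spell (tmin ≤ −10 °C) beginning on or
    after the start.  A frost-free window caps the end at 30 April with
    :data:`FLAG_FH_NO_FROST_CAPPED`; when the start cannot precede a
    frost day (or never hardens at all) the span is reported absent with
    :data:`FLAG_FH_DEGENERATE`.
    """
    start_window = dt.date(season_year - 1, 8, 1)
    end_window = dt.date(season_year, *FH_SEARCH_END)
    win = series.window(start_window, end_window)

    tmean = win["tmean"].to_numpy(float)
    balance = np.cumsum(np.maximum(0.0, HARDENING_BASE - tmean)
                        - np.maximum(0.0, tmean - HARDENING_BASE))
    nonpos = balance <= _BALANCE_TOL
    n = len(win)
    if not nonpos.any():
        start_idx = 0  # balance positive from day one: start at 1 August
    else:
        start_idx = int(np.flatnonzero(nonpos)[-1])

    frost_runs = _run_bounds(win["tmin"].to_numpy(float) <= FH_FROST_THRESHOLD)
    dates = win.index.date

    if frost_runs:
        eligible = [(s, e) for s, e in frost_runs if s >= start_idx]
        if not eligible:
            # every frost spell precedes the computed start
            return None, frozenset({FLAG_FH_DEGENERATE})
        _, end_idx = eligible[0]
        return PeriodSpan(dates[start_idx], dates[end_idx]), frozenset()

    if start_idx == n - 1:
        # balance never returned to positive and no frost occurred
        return None, frozenset({FLAG_FH_NO_FROST_CAPPED, FLAG_FH_DEGENERATE})
    return (
        PeriodSpan(dates[start_idx], dates[n - 1]),
        frozenset({FLAG_FH_NO_FROST_CAPPED}),
    )


def find_growth_period_start(
    series: WeatherSeries, season_year: int
) -> tuple[dt.date | None, frozenset[str]]:
    """Fifth day of the first 5-day spell with tmean > 5 °C.

    Searches 1 January to 31 July of ``season_year``; absent (with
    :data:`FLAG_NO_GP_SPELL`) when no such spell occurs.
    """
    win = series.window(dt.date(season_year, 1, 1), dt.date(season_year, 7, 31))
    warm = win["tmean"].to_numpy(float) > GP_SPELL_THRESHOLD
    for s, e in _run_bounds(warm):
        if e - s + 1 >= GP_SPELL_DAYS:
            return win.index.date[s + GP_SPELL_DAYS - 1], frozenset()
    return None, frozenset({FLAG_NO_GP_SPELL})


def segment_season(
    series: WeatherSeries,
    season_year: int,
    last_harvest: dt.date,
) -> SeasonSegmentation:
    """Compose FH, WP and GP for one site-season.

    ``last_harvest`` (the season's final cut) closes the GP.  Missing
    weather yields an all-absent segmentation flagged
    :data:`FLAG_INCOMPLETE_WEATHER` rather than an exception, so whole
    trial networks can be segmented with per-season accounting.
    """
    one_day = dt.timedelta(days=1)
    flags: set[str] = set()
    try:
        fh, fh_flags = find_fall_hardening(series, season_year)
        gp_start, gp_flags = find_growth_period_start(series, season_year)
    except IncompleteWeatherError:
        return SeasonSegmentation(
            series.site_id, season_year, flags=frozenset({FLAG_INCOMPLETE_WEATHER})
        )
    flags |= fh_flags | gp_flags

    gp = None
    if gp_start is not None:
        if last_harvest < gp_start:
            raise ValueError(
                f"site {series.site_id} season {season_year}: last harvest "
                f"{last_harvest} precedes GP start {gp_start}"
            )
        gp = PeriodSpan(gp_start, last_harvest)

    wp = None
    if fh is not None and gp_start is not None:
        wp_start, wp_end = fh.end + one_day, gp_start - one_day
        if wp_start <= wp_end:
            wp = PeriodSpan(wp_start, wp_end)

    return SeasonSegmentation(series.site_id, season_year, fh, wp, gp, frozenset(flags))


# ---------------------------------------------------------------------------
# CSV interfaces

WEATHER_COLUMNS = ["site_id", "date", "tmean_c", "tmin_c", "tmax_c", "precip_mm"]


def read_weather_csv(path) -> dict[str, WeatherSeries]:
    """Read a per-site-day weather CSV into :class:`WeatherSeries` by site.

    Expects columns ``site_id, date, tmean_c, tmin_c, tmax_c, precip_mm``
    (ISO dates, one row per site-day); duplicate site-days are rejected.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV lacks columns {sorted(missing)}")
    out: dict[str, WeatherSeries] = {}
    for site, grp in df.groupby("site_id", sort=True):
        frame = grp.set_index("date")[["tmean_c", "tmin_c", "tmax_c", "precip_mm"]]
        frame.columns = ["tmean", "tmin", "tmax", "precip"]
        out[str(site)] = WeatherSeries(str(site), frame)
    return out


def weather_to_frame(series_by_site: dict[str, WeatherSeries]) -> pd.DataFrame:
    """Inverse of :func:`read_weather_csv`: tidy frame in the CSV dialect."""
    parts = []
    for site, ws in series_by_site.items():
        f = ws.frame.reset_index(names="date")
        f.insert(0, "site_id", site)
        f.columns = WEATHER_COLUMNS
        parts.append(f)
    return pd.concat(parts, ignore_index=True)


def write_segmentation_csv(segmentations, path) -> pd.DataFrame:
    """Write one row per site-season with span endpoints and flags."""
    rows = []
    for seg in segmentations:
        rows.append(
            {
                "site_id": seg.site_id,
                "season_year": seg.season_year,
                "fh_start": seg.fh.start.isoformat() if seg.fh else "",
                "fh_end": seg.fh.end.isoformat() if seg.fh else "",
                "wp_start": seg.wp.start.isoformat() if seg.wp else "",
                "wp_end": seg.wp.end.isoformat() if seg.wp else "",
                "gp_start": seg.gp.start.isoformat() if seg.gp else "",
                "gp_end": seg.gp.end.isoformat() if seg.gp else "",
                "flags": ";".join(sorted(seg.flags)),
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(path, index=False)
    return out
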