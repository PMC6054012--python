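"""The 14 agroclimatic variables computed per trial environment.

Each variable aggregates daily weather over a window anchored to the
season segmentation (FH / WP / GP) or to the cut schedule of one trial.
Cut dates differ between experiments at the same site-year, so
GP-anchored values are computed per experiment, not per site-year.

A variable that cannot be computed (absent or flagged span, missing
second cut, missing weather) is *missing with a reason*, never a silent
zero; downstream stages propagate the missingness.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .weather import (
    FLAG_FH_DEGENERATE,
    FLAG_FH_NO_FROST_CAPPED,
    IncompleteWeatherError,
    PeriodSpan,
    SeasonSegmentation,
    WeatherSeries,
)

__all__ = [
    "CutSchedule",
    "EnvironmentUnit",
    "VariableResult",
    "VARIABLE_REGISTRY",
    "VARIABLE_IDS",
    "degree_day_sum",
    "count_days",
    "compute_variable",
    "compute_all_variables",
]

logger = logging.getLogger(__name__)

POSTCUT_TSUM_DAYS = 7
POSTCUT_RAIN_DAYS = 14
HEAT_THRESHOLD = 25.0       # °C, tmax
SEVERE_HEAT_THRESHOLD = 28.0
COLD_STRESS_THRESHOLD = -15.0  # °C, tmin


@dataclass(frozen=True)
class CutSchedule:
    """Harvest dates of one trial season (two to three cuts)."""

    cut1: dt.date
    last_cut: dt.date
    cut2: dt.date | None = None

    def __post_init__(self) -> None:
        if self.cut2 is not None and not (self.cut1 < self.cut2 <= self.last_cut):
            raise ValueError("cuts must satisfy cut1 < cut2 <= last_cut")
        if self.cut1 > self.last_cut:
            raise ValueError("cut1 must not be after last_cut")


@dataclass(frozen=True)
class EnvironmentUnit:
    """One site × harvest-year × experiment environment."""

    site_id: str
    experiment_id: str
    harvest_year: int
    segmentation: SeasonSegmentation
    cuts: CutSchedule

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.site_id, self.harvest_year, self.experiment_id)


class VariableResult(NamedTuple):
    value: float | None
    reason: str | None

    @property
    def is_missing(self) -> bool:
        return self.value is None


@dataclass(frozen=True)
class VariableSpec:
    """Machine-readable description of one agroclimatic variable."""

    id: str
    period: str        # FH | WP | GP
    window: str        # span | gp_to_cut1 | cut1_to_cut2 | post_cut1
    field: str         # tmean | tmin | tmax | precip
    aggregation: str   # length | dd_below | dd_above | sum | mean_per_day | count_ge | count_le
    threshold: float | None
    units: str
    description: str


VARIABLE_REGISTRY: dict[str, VariableSpec] = {
    s.id: s
    for s in [
        VariableSpec("FH_LENGTH", "FH", "span", "tmean", "length", None, "days",
                     "Length of the fall-hardening period"),
        VariableSpec("FH_COLD5", "FH", "span", "tmean", "dd_below", 5.0, "degree-days",
                     "Accumulation of cold temperatures below 5 °C during FH"),
        VariableSpec("FH_RAIN", "FH", "span", "precip", "mean_per_day", None, "mm",
                     "Mean daily rainfall during FH"),
        VariableSpec("WP_WARM0_RATE", "WP", "span", "tmean", "mean_warm", 0.0, "degree-days",
                     "Mean daily accumulation of temperature above 0 °C during WP"),
        VariableSpec("WP_STRESS15", "WP", "span", "tmin", "count_le", COLD_STRESS_THRESHOLD,
                     "days", "Cold stress days with minimum temperature at or below −15 °C"),
        VariableSpec("GP_TSUM5", "GP", "span", "tmean", "dd_above", 5.0, "degree-days",
                     "Temperature sum above 5 °C over the growth period"),
        VariableSpec("GP_TSUM_RATE", "GP", "span", "tmean", "rate_above", 5.0,
                     "degree-days/day", "Mean daily temperature-sum accumulation rate"),
        VariableSpec("GP_HOT25_CUT1", "GP", "gp_to_cut1", "tmax", "count_ge", HEAT_THRESHOLD,
                     "days", "Days with maximum temperature ≥ 25 °C, GP start to 1st cut"),
        VariableSpec("GP_HOT25_CUT2", "GP", "cut1_to_cut2", "tmax", "count_ge", HEAT_THRESHOLD,
                     "days", "Days with maximum temperature ≥ 25 °C, 1st to 2nd cut"),
        VariableSpec("GP_HOT28", "GP", "span", "tmax", "count_ge", SEVERE_HEAT_THRESHOLD,
                     "days", "Days with maximum temperature ≥ 28 °C in the GP"),
        VariableSpec("GP_POSTCUT_TSUM7", "GP", "post_cut1_7", "tmean", "sum_warm", 0.0,
                     "degree-days", "Temperature sum in the 7 days after the 1st cut"),
        VariableSpec("GP_RAIN_CUT1", "GP", "gp_to_cut1", "precip", "sum", None, "mm",
                     "Precipitation from GP start to 1st cut"),
        VariableSpec("GP_RAIN_CUT2", "GP", "cut1_to_cut2", "precip", "sum", None, "mm",
                     "Precipitation from 1st to 2nd cut"),
        VariableSpec("GP_POSTCUT_RAIN14", "GP", "post_cut1_14", "precip", "sum", None, "mm",
                     "Precipitation in the 14 days after the 1st cut"),
    ]
}

VARIABLE_IDS: tuple[str, ...] = tuple(VARIABLE_REGISTRY)
assert len(VARIABLE_IDS) == 14


def degree_day_sum(
    series: WeatherSeries, span: PeriodSpan, base: float, direction: str
) -> float:
    """Degree-day accumulation of daily means over an inclusive span.

    ``direction='above'`` sums ``max(0, tmean − base)``; ``'below'`` sums
    ``max(0, base − tmean)``.
    """
    tmean = series.window(span.start, span.end)["tmean"].to_numpy(float)
    if direction == "above":
        return float(np.maximum(0.0, tmean - base).sum())
    if direction == "below":
        return float(np.maximum(0.0, base - tmean).sum())
    raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")


def count_days(
    series: WeatherSeries, span: PeriodSpan, field: str, threshold: float, cmp: str
) -> int:
    """Number of days in the span whose ``field`` meets the comparison."""
    if field not in ("tmin", "tmax", "tmean"):
        raise ValueError(f"unknown temperature field {field!r}")
    vals = series.window(span.start, span.end)[field].to_numpy(float)
    if cmp == "ge":
        return int((vals >= threshold).sum())
    if cmp == "le":
        return int((vals <= threshold).sum())
    raise ValueError(f"cmp must be 'ge' or 'le', got {cmp!r}")


def _fh_status(seg: SeasonSegmentation) -> str | None:
    if seg.fh is None:
        return "fh_absent"
    if seg.flags & {FLAG_FH_NO_FROST_CAPPED, FLAG_FH_DEGENERATE}:
        return "fh_flagged"
    return None


def _resolve_window(
    spec: VariableSpec, unit: EnvironmentUnit
) -> tuple[PeriodSpan | None, str | None]:
    """Map a registry window name to a concrete date span (or a missing reason)."""
    seg, cuts = unit.segmentation, unit.cuts
    one = dt.timedelta(days=1)
    if spec.period == "FH":
        reason = _fh_status(seg)
        return (None, reason) if reason else (seg.fh, None)
    if spec.period == "WP":
        return (seg.wp, None) if seg.wp is not None else (None, "wp_absent")
    if seg.gp is None:
        return None, "gp_absent"
    if spec.window == "span":
        return seg.gp, None
    if spec.window == "gp_to_cut1":
        return PeriodSpan(seg.gp.start, cuts.cut1), None
    if spec.window == "cut1_to_cut2":
        if cuts.cut2 is None:
            return None, "cut2_absent"
        return PeriodSpan(cuts.cut1 + one, cuts.cut2), None
    if spec.window == "post_cut1_7":
        return PeriodSpan(cuts.cut1 + one, cuts.cut1 + POSTCUT_TSUM_DAYS * one), None
    if spec.window == "post_cut1_14":
        return PeriodSpan(cuts.cut1 + one, cuts.cut1 + POSTCUT_RAIN_DAYS * one), None
    raise AssertionError(f"unhandled window {spec.window!r}")


def compute_variable(
    unit: EnvironmentUnit, series: WeatherSeries, var_id: str
) -> VariableResult:
    """Value of one agroclimatic variable for one environment unit."""
    spec = VARIABLE_REGISTRY[var_id]
    span, reason = _resolve_window(spec, unit)
    if span is None:
        return VariableResult(None, reason)
    try:
        win = series.window(span.start, span.end)
    except IncompleteWeatherError:
        return VariableResult(None, "incomplete_weather")

    agg = spec.aggregation
    if agg == "length":
        return VariableResult(float(span.length_days), None)
    if agg == "dd_below":
        return VariableResult(degree_day_sum(series, span, spec.threshold, "below"), None)
    if agg == "dd_above":
        return VariableResult(degree_day_sum(series, span, spec.threshold, "above"), None)
    if agg == "rate_above":
        total = degree_day_sum(series, span, spec.threshold, "above")
        return VariableResult(total / span.length_days, None)
    if agg == "sum":
        return VariableResult(float(win[spec.field].sum()), None)
    if agg == "mean_per_day":
        return VariableResult(float(win[spec.field].sum()) / span.length_days, None)
    if agg == "sum_warm":
        warm = np.maximum(0.0, win[spec.field].to_numpy(float) - spec.threshold)
        return VariableResult(float(warm.sum()), None)
    if agg == "mean_warm":
        warm = np.maximum(0.0, win[spec.field].to_numpy(float) - spec.threshold)
        return VariableResult(float(warm.sum()) / span.length_days, None)
    if agg == "count_ge":
        return VariableResult(
            float(count_days(series, span, spec.field, spec.threshold, "ge")), None
        )
    if agg == "count_le":
        return VariableResult(
            float(count_days(series, span, spec.field, spec.threshold, "le")), None
        )
    raise AssertionError(f"unhandled aggregation {agg!r}")


def compute_all_variables(
    units: list[EnvironmentUnit], weather: dict[str, WeatherSeries]
) -> pd.DataFrame:
    """One row per unit with all 14 variables and companion reason columns.

    Raises on a unit whose site has no weather series; logs a summary of
    missingness reasons.
    """
    rows = []
    reason_counts: dict[str, int] = {}
    for unit in units:
        if unit.site_id not in weather:
            raise KeyError(f"no weather series configured for site {unit.site_id!r}")
        series = weather[unit.site_id]
        row: dict[str, object] = {
            "site_id": unit.site_id,
            "experiment_id": unit.experiment_id,
            "harvest_year": unit.harvest_year,
        }
        for var_id in VARIABLE_IDS:
            res = compute_variable(unit, series, var_id)
            row[var_id] = np.nan if res.value is None else res.value
            row[f"{var_id}_reason"] = res.reason or ""
            if res.reason:
                reason_counts[res.reason] = reason_counts.get(res.reason, 0) + 1
        rows.append(row)
    if reason_counts:
        logger.info("missing-variable reasons: %s", dict(sorted(reason_counts.items())))
    return pd.DataFrame(rows)
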