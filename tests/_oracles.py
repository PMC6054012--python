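"""Independent brute-force oracles used by the test suite.

Deliberately naive: day-by-day scans and exhaustive enumeration, written
directly from the period/partition rules, with no code shared with the
package implementation.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd


def fh_oracle(series, season_year):
    """Literal day-scan for the fall-hardening span.

    Returns (span_start, span_end) as dates, or (None, None) with the
    same absent semantics as the engine: degenerate when every frost
    spell precedes the balance start or the balance never recovers and
    no frost occurs; capped at 30 April when frost never occurs.
    """
    first = dt.date(season_year - 1, 8, 1)
    last = dt.date(season_year, 4, 30)
    days = []
    d = first
    while d <= last:
        days.append(d)
        d += dt.timedelta(days=1)
    frame = series.window(first, last)

    # last day with S(d) <= 0, recomputing the sum from scratch each day
    start = None
    for i in range(len(days) - 1, -1, -1):
        s = 0.0
        for j in range(i + 1):
            t = float(frame["tmean"].iloc[j])
            if t < 5.0:
                s += 5.0 - t
            else:
                s -= t - 5.0
        if s <= 1e-9:
            start = days[i]
            break
    if start is None:
        start = first

    # frost spells: scan every day
    frost = [bool(frame["tmin"].iloc[i] <= -10.0) for i in range(len(days))]
    spells = []
    i = 0
    while i < len(days):
        if frost[i]:
            j = i
            while j + 1 < len(days) and frost[j + 1]:
                j += 1
            spells.append((days[i], days[j]))
            i = j + 1
        else:
            i += 1

    after = [sp for sp in spells if sp[0] >= start]
    if after:
        return start, after[0][1]
    if spells:
        return None, None  # degenerate: frost only before the start
    if start == last:
        return None, None  # never hardened, never froze
    return start, last  # capped


def gp_oracle(series, season_year):
    """Check every 5-day window for the first warm spell."""
    first = dt.date(season_year, 1, 1)
    last = dt.date(season_year, 7, 31)
    frame = series.window(first, last)
    tm = frame["tmean"].to_numpy(float)
    for i in range(len(tm) - 4):
        if all(tm[i + k] > 5.0 for k in range(5)):
            return first + dt.timedelta(days=i + 4)
    return None


def degree_day_loop(frame: pd.DataFrame, base: float, direction: str) -> float:
    total = 0.0
    for t in frame["tmean"]:
        if direction == "below" and t < base:
            total += base - t
        if direction == "above" and t > base:
            total += t - base
    return total


def count_days_loop(frame: pd.DataFrame, field: str, threshold: float, cmp: str) -> int:
    n = 0
    for v in frame[field]:
        if cmp == "ge" and v >= threshold:
            n += 1
        if cmp == "le" and v <= threshold:
            n += 1
    return n


def tertile_partition_oracle(values: np.ndarray, counts: np.ndarray) -> float:
    """Minimum achievable max deviation from N/3 over all valid partitions.

    Enumerates every pair of split points in the sorted unit order,
    discarding partitions that separate tied values or leave a category
    empty.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    c = counts[order]
    n_units = len(v)
    total = c.sum()
    target = total / 3.0
    best = np.inf
    for i in range(1, n_units - 1):
        if v[i - 1] == v[i]:
            continue
        for j in range(i + 1, n_units):
            if v[j - 1] == v[j]:
                continue
            parts = (c[:i].sum(), c[i:j].sum(), c[j:].sum())
            cost = max(abs(p - target) for p in parts)
            best = min(best, cost)
    return best


def balanced_anova_f(df: pd.DataFrame, response: str = "annual_dm_yield_kg_ha"):
    """Closed-form two-way fixed-effects ANOVA on balanced cell data.

    Returns F statistics for the cultivar main effect, the category main
    effect and their interaction, from the textbook sums of squares.
    """
    y = df[response].to_numpy(float)
    a_lab = df["cultivar"].to_numpy()
    b_lab = df["category"].to_numpy()
    a_levels = sorted(set(a_lab))
    b_levels = sorted(set(b_lab))
    a, b = len(a_levels), len(b_levels)
    cell_n = len(df) // (a * b)
    grand = y.mean()
    ss_a = sum(
        b * cell_n * (y[a_lab == la].mean() - grand) ** 2 for la in a_levels
    )
    ss_b = sum(
        a * cell_n * (y[b_lab == lb].mean() - grand) ** 2 for lb in b_levels
    )
    ss_cells = 0.0
    ss_resid = 0.0
    for la in a_levels:
        for lb in b_levels:
            cell = y[(a_lab == la) & (b_lab == lb)]
            ss_cells += cell_n * (cell.mean() - grand) ** 2
            ss_resid += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_resid = len(y) - a * b
    mse = ss_resid / df_resid
    return {
        "G": (ss_a / df_a) / mse,
        "E": (ss_b / df_b) / mse,
        "GxE": (ss_ab / df_ab) / mse,
    }
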