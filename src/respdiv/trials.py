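"""Variety-trial observations: cut-date imputation, cultivar selection,
tertile categorization.

Observations live in a tidy DataFrame (one row per cultivar × trial ×
year) carrying the annual dry-matter yield and the trial's cut schedule.
An *environment unit* is one site × harvest-year × experiment; every
observation of a unit shares the unit's cut dates, agroclimatic values
and, after categorization, its low/moderate/high label.
"""

from __future__ import annotations

import datetime as dt
import itertools
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "TRIAL_COLUMNS",
    "UNIT_KEY",
    "read_trials_csv",
    "impute_missing_cut_dates",
    "select_reporting_set",
    "categorize_tertiles",
    "classify_value",
    "attach_categories",
]

SPECIES = ("timothy", "meadow_fescue", "tall_fescue", "festulolium", "red_clover")

TRIAL_COLUMNS = [
    "site_id", "experiment_id", "harvest_year", "species", "cultivar", "origin",
    "annual_dm_yield_kg_ha", "cut1_date", "cut2_date", "last_cut_date",
]

UNIT_KEY = ["site_id", "harvest_year", "experiment_id"]

_CUT_SLOTS = ("cut1_date", "cut2_date", "last_cut_date")


def read_trials_csv(path) -> pd.DataFrame:
    """Read the trial CSV; empty date cells become NaT (missing)."""
    df = pd.read_csv(path, parse_dates=list(_CUT_SLOTS))
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV lacks columns {sorted(missing)}")
    unknown = set(df["species"].unique()) - set(SPECIES)
    if unknown:
        raise ValueError(f"unknown species {sorted(unknown)}")
    if (df["annual_dm_yield_kg_ha"] <= 0).any():
        bad = df.index[df["annual_dm_yield_kg_ha"] <= 0].tolist()[:5]
        raise ValueError(f"non-positive yields at rows {bad}")
    return df


def write_trials_csv(df: pd.DataFrame, path) -> None:
    out = df[TRIAL_COLUMNS].copy()
    for col in _CUT_SLOTS:
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cut-date imputation

def _doy(ts) -> float:
    return float(pd.Timestamp(ts).dayofyear)


def _date_from_doy(year: int, doy: float) -> dt.date:
    return dt.date(year, 1, 1) + dt.timedelta(days=int(round(doy)) - 1)


def impute_missing_cut_dates(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing cut dates from the rest of the trial network.

    The imputation model regresses harvest day-of-year on species and
    cut-number fixed effects with a site × year random intercept, i.e. a
    missing date is predicted from the harvest dates of other cultivars
    at the same site and year, adjusted for species and cut number.
    Predictions are rounded to whole days and clamped inside the
    observed harvest-date range of the site-year.  When the model is
    degenerate (no residual variation) it collapses to the group mean.

    A missing second cut is imputed only when the same site-year has an
    observed second cut somewhere (otherwise the trial is taken to be a
    two-cut trial).  A site-year with no observed dates at all cannot
    donate; its observations are flagged in ``excluded_reason`` and left
    unimputed, mirroring the rule that trials with missing growing-season
    data drop out of variable estimation.

    Returns the completed frame and a log with one row per imputed field.
    """
    df = df.copy()
    if "excluded_reason" not in df.columns:
        df["excluded_reason"] = ""

    long_rows = []
    for slot_num, slot in enumerate(_CUT_SLOTS, start=1):
        obs = df[df[slot].notna()]
        for idx, row in obs.iterrows():
            long_rows.append(
                {
                    "obs_index": idx,
                    "site_year": f"{row.site_id}|{row.harvest_year}",
                    "species": row.species,
                    "slot": slot_num,
                    "doy": _doy(row[slot]),
                }
            )
    observed = pd.DataFrame(long_rows)
    if observed.empty:
        raise ValueError("no observed cut dates anywhere in the dataset")

    n_missing = int(df[list(_CUT_SLOTS)].isna().sum().sum())
    if n_missing == 0:
        return df, pd.DataFrame(
            columns=["obs_index", "field", "imputed_doy", "imputed_date",
                     "n_donors_site_year", "method"]
        )

    slot_means = observed.groupby("slot")["doy"].mean()
    group_slot_means = observed.groupby(["site_year", "slot"])["doy"].mean()
    group_resid_means = (
        observed.assign(resid=observed["doy"] - observed["slot"].map(slot_means))
        .groupby("site_year")["resid"].mean()
    )
    species_slot_means = observed.groupby(["species", "slot"])["doy"].mean()

    model_fit = None
    resid_within = observed["doy"] - observed.set_index(["site_year", "slot"]).index.map(
        group_slot_means
    )
    if float(np.nanvar(resid_within)) > 1e-12:
        try:
            import statsmodels.formula.api as smf

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model_fit = smf.mixedlm(
                    "doy ~ C(species) + C(slot)", observed, groups=observed["site_year"]
                ).fit(reml=True)
            if not np.all(np.isfinite(model_fit.fe_params)):
                model_fit = None
        except Exception:
            model_fit = None

    log_rows = []
    site_year_has_cut2 = set(observed.loc[observed["slot"] == 2, "site_year"])
    observed_sy = set(observed["site_year"])
    sy_range = observed.groupby("site_year")["doy"].agg(["min", "max"])

    for idx, row in df[df[list(_CUT_SLOTS)].isna().any(axis=1)].iterrows():
        site_year = f"{row.site_id}|{row.harvest_year}"
        if site_year not in observed_sy:
            df.at[idx, "excluded_reason"] = "no_observed_cut_dates_in_site_year"
            continue
        for slot_num, slot in enumerate(_CUT_SLOTS, start=1):
            if pd.notna(row[slot]):
                continue
            if slot_num == 2 and site_year not in site_year_has_cut2:
                continue  # two-cut trial, nothing to impute
            donors = int((observed["site_year"] == site_year).sum())
            pred, method = None, None
            if model_fit is not None:
                try:
                    new = pd.DataFrame(
                        {"species": [row.species], "slot": [slot_num]}
                    )
                    fixed = float(model_fit.predict(new).iloc[0])
                    blup = float(
                        model_fit.random_effects.get(
                            site_year, pd.Series([0.0])
                        ).iloc[0]
                    )
                    pred, method = fixed + blup, "mixed_model"
                except Exception:
                    pred = None
            if pred is None or not np.isfinite(pred):
                key = (site_year, slot_num)
                if key in group_slot_means.index:
                    pred, method = float(group_slot_means[key]), "site_year_slot_mean"
                elif site_year in group_resid_means.index and slot_num in slot_means.index:
                    pred = float(slot_means[slot_num] + group_resid_means[site_year])
                    method = "site_year_offset"
                elif (row.species, slot_num) in species_slot_means.index:
                    pred = float(species_slot_means[(row.species, slot_num)])
                    method = "species_slot_mean"
                else:
                    pred, method = float(slot_means[slot_num]), "slot_mean"
            lo, hi = sy_range.loc[site_year, "min"], sy_range.loc[site_year, "max"]
            pred = float(np.clip(pred, lo, hi))
            doy = int(round(pred))
            imputed = _date_from_doy(int(row.harvest_year), doy)
            df.at[idx, slot] = pd.Timestamp(imputed)
            log_rows.append(
                {
                    "obs_index": idx,
                    "field": slot,
                    "imputed_doy": doy,
                    "imputed_date": imputed.isoformat(),
                    "n_donors_site_year": donors,
                    "method": method,
                }
            )

    # ordering sanity after imputation
    for idx, row in df.iterrows():
        c1, c2, cl = row["cut1_date"], row["cut2_date"], row["last_cut_date"]
        if pd.notna(c1) and pd.notna(cl) and c1 > cl:
            df.at[idx, "excluded_reason"] = "imputed_cut_order_violation"
        elif pd.notna(c2) and (
            (pd.notna(c1) and not c1 < c2) or (pd.notna(cl) and not c2 <= cl)
        ):
            df.at[idx, "excluded_reason"] = "imputed_cut_order_violation"

    return df, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# Reporting-set selection

def select_reporting_set(
    df: pd.DataFrame,
    usable: pd.Series | None = None,
    year_range: tuple[int, int] = (2000, 2012),
    min_obs: int = 20,
) -> tuple[pd.DataFrame, list[str]]:
    """Split estimation data from the cultivars reported on.

    The *estimation set* is the entire frame — long-term control
    cultivars stabilize the yield estimates of modern ones.  The
    *reporting set* contains cultivars tested inside ``year_range``
    with at least ``min_obs`` usable observations, where ``usable``
    marks observations with a non-missing value of the variable under
    analysis (all observations by default).  Selection is idempotent.
    """
    if usable is None:
        usable = pd.Series(True, index=df.index)
    usable = usable.reindex(df.index, fill_value=False)
    in_range = df["harvest_year"].between(*year_range)
    counts = df.loc[in_range & usable].groupby("cultivar").size()
    reporting = sorted(counts.index[counts >= min_obs])
    if not reporting:
        raise ValueError(
            f"no cultivar reaches {min_obs} usable observations in "
            f"{year_range[0]}–{year_range[1]}"
        )
    return df, reporting


# ---------------------------------------------------------------------------
# Tertile categorization

CATEGORY_LEVELS = ("low", "moderate", "high")


def categorize_tertiles(
    unit_values: pd.Series, obs_counts: pd.Series
) -> tuple[pd.Series, tuple[float, float]]:
    """Split environment units into low/moderate/high thirds of a variable.

    ``unit_values`` maps unit keys to the unit's value of the variable;
    ``obs_counts`` gives the number of trial observations per unit.
    Categories are contiguous in value order, every unit's observations
    stay together, and tied unit values share a label; subject to those
    constraints the partition minimizes the largest deviation of any
    category's observation count from N/3 (ties broken deterministically
    by boundary position).  Returns per-unit labels and the two
    breakpoints — the largest value in the low and moderate categories —
    so a value v classifies as low (v ≤ b1), moderate (b1 < v ≤ b2) or
    high (v > b2).
    """
    vals = unit_values.dropna()
    if len(vals) < 3:
        raise ValueError("need at least 3 units with non-missing values")
    counts = obs_counts.reindex(vals.index)
    if counts.isna().any():
        raise ValueError("obs_counts missing for some units")

    order = vals.sort_values(kind="mergesort")
    blocks: list[tuple[float, list, int]] = []  # (value, unit keys, obs count)
    for value, grp in order.groupby(order.values, sort=True):
        keys = list(grp.index)
        blocks.append((float(value), keys, int(counts.loc[keys].sum())))
    if len(blocks) == 1:
        raise ValueError("degenerate distribution: all units share one value")
    if len(blocks) == 2:
        raise ValueError("cannot form three categories from two distinct values")

    block_counts = np.array([b[2] for b in blocks])
    total = block_counts.sum()
    target = total / 3.0
    cum = np.concatenate([[0], np.cumsum(block_counts)])

    best, best_cost = None, np.inf
    for i, j in itertools.combinations(range(1, len(blocks)), 2):
        c = (cum[i], cum[j] - cum[i], total - cum[j])
        cost = max(abs(x - target) for x in c)
        if cost < best_cost - 1e-12:
            best, best_cost = (i, j), cost
    i, j = best

    labels = {}
    for b, (_, keys, _) in enumerate(blocks):
        lab = "low" if b < i else ("moderate" if b < j else "high")
        for k in keys:
            labels[k] = lab
    breakpoints = (blocks[i - 1][0], blocks[j - 1][0])
    return pd.Series(labels).reindex(unit_values.index), breakpoints


def classify_value(value: float, breakpoints: tuple[float, float]) -> str:
    b1, b2 = breakpoints
    if value <= b1:
        return "low"
    if value <= b2:
        return "moderate"
    return "high"


def unit_id_series(df: pd.DataFrame) -> pd.Series:
    """Canonical ``site|year|experiment`` unit identifier per observation."""
    return (
        df["site_id"].astype(str)
        + "|"
        + df["harvest_year"].astype(str)
        + "|"
        + df["experiment_id"].astype(str)
    )


def attach_categories(
    df: pd.DataFrame,
    unit_values: pd.Series,
    var_id: str,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Label every observation with its unit's tertile of one variable.

    ``unit_values`` is indexed by the ``site|year|experiment`` unit id
    (see :func:`unit_id_series`).  Observations of units with a missing
    value get a missing label and are dropped by the model stage.
    """
    keys = unit_id_series(df)
    obs_counts = keys.value_counts().reindex(unit_values.index, fill_value=0)
    usable_units = unit_values.dropna().index
    labels, breakpoints = categorize_tertiles(
        unit_values.loc[usable_units], obs_counts.loc[usable_units]
    )
    out = df.copy()
    out["unit"] = keys.to_numpy()
    out["variable_id"] = var_id
    out["unit_value"] = keys.map(unit_values).to_numpy()
    out["category"] = keys.map(labels).to_numpy()
    out["breakpoint_low_moderate"] = breakpoints[0]
    out["breakpoint_moderate_high"] = breakpoints[1]
    return out, breakpoints
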