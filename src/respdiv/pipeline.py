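"""Pipeline orchestration: segment → variables → categorize → fit → assess.

Every stage consumes and produces plain CSV, so intermediate results
are inspectable, and a JSON manifest records the configuration, seed,
package versions and per-stage counts.  Reruns with the same inputs and
seed reproduce identical result files.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .weather import (
    WeatherSeries,
    read_weather_csv,
    segment_season,
    write_segmentation_csv,
)
from .variables import (
    VARIABLE_IDS,
    CutSchedule,
    EnvironmentUnit,
    compute_all_variables,
)
from .trials import (
    SPECIES,
    attach_categories,
    impute_missing_cut_dates,
    read_trials_csv,
    select_reporting_set,
    unit_id_series,
)
from .gxe import fit_gxe_model, response_profile, summarize_species

logger = logging.getLogger(__name__)

RESULT_FILES = (
    "segmentation.csv",
    "variables.csv",
    "categories.csv",
    "results.csv",
    "profiles.csv",
)


@dataclass
class PipelineConfig:
    weather_csv: str | None = None
    trials_csv: str | None = None
    outdir: str = "out"
    variables: tuple[str, ...] = VARIABLE_IDS
    alpha_e: float = 0.05
    alpha_gxe: float = 0.05
    df_method: str = "satterthwaite"
    year_range: tuple[int, int] = (2000, 2012)
    min_obs: int = 20
    seed: int = 0
    strict: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for a in (self.alpha_e, self.alpha_gxe):
            if not 0.0 < a < 1.0:
                raise ValueError("significance thresholds must lie in (0, 1)")
        unknown = set(self.variables) - set(VARIABLE_IDS)
        if unknown:
            raise ValueError(f"unknown variable ids {sorted(unknown)}")
        if self.df_method not in ("satterthwaite", "residual"):
            raise ValueError("df_method must be 'satterthwaite' or 'residual'")


def load_config(path) -> PipelineConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "variables" in raw and raw["variables"]:
        raw["variables"] = tuple(raw["variables"])
    if "year_range" in raw:
        raw["year_range"] = tuple(raw["year_range"])
    return PipelineConfig(**raw)


def validate_inputs(
    weather: dict[str, WeatherSeries], trials: pd.DataFrame
) -> pd.DataFrame:
    """Non-fatal input QC: one row per issue (empty frame = clean)."""
    issues = []
    for site, ws in weather.items():
        if ws.missing_days:
            days = sorted(ws.missing_days)
            issues.append(
                {"kind": "non_contiguous_weather", "where": site,
                 "detail": f"{len(days)} missing days, first {days[0].isoformat()}"}
            )
    for idx, row in trials.iterrows():
        c1, c2, cl = row.get("cut1_date"), row.get("cut2_date"), row.get("last_cut_date")
        if pd.notna(c1) and pd.notna(c2) and not c1 < c2:
            issues.append(
                {"kind": "cut_order_violation", "where": f"row {idx}",
                 "detail": f"cut2 {c2} not after cut1 {c1}"}
            )
        elif pd.notna(c2) and pd.notna(cl) and not c2 <= cl:
            issues.append(
                {"kind": "cut_order_violation", "where": f"row {idx}",
                 "detail": f"last cut {cl} before cut2 {c2}"}
            )
    unknown_species = set(trials["species"].unique()) - set(SPECIES)
    for sp in sorted(unknown_species):
        issues.append({"kind": "unknown_species", "where": sp, "detail": ""})
    bad_yield = trials.index[
        (trials["annual_dm_yield_kg_ha"] <= 0)
        | (trials["annual_dm_yield_kg_ha"] > 30000)
    ]
    for idx in bad_yield:
        issues.append(
            {"kind": "out_of_range_yield", "where": f"row {idx}",
             "detail": str(trials.at[idx, "annual_dm_yield_kg_ha"])}
        )
    missing_weather = set(trials["site_id"].astype(str)) - set(weather)
    for site in sorted(missing_weather):
        issues.append({"kind": "site_without_weather", "where": site, "detail": ""})
    return pd.DataFrame(issues, columns=["kind", "where", "detail"])


def build_environment_units(
    trials: pd.DataFrame, weather: dict[str, WeatherSeries]
) -> tuple[list[EnvironmentUnit], pd.Series]:
    """One unit per site × year × experiment with its shared cut schedule.

    Returns the units and a per-observation exclusion-reason series
    (empty string = eligible).  A unit needs a first and last cut date
    and weather coverage; its cut dates are the unit group's dates.
    """
    reasons = pd.Series("", index=trials.index, dtype=object)
    if "excluded_reason" in trials.columns:
        reasons = trials["excluded_reason"].fillna("").astype(object).copy()
    units: list[EnvironmentUnit] = []
    uid = unit_id_series(trials)
    for key, grp in trials.groupby(uid.rename("unit"), sort=True):
        eligible = grp.index[reasons.loc[grp.index] == ""]
        if len(eligible) == 0:
            continue
        row = grp.loc[eligible[0]]
        site = str(row["site_id"])
        if site not in weather:
            reasons.loc[eligible] = "site_without_weather"
            continue
        if pd.isna(row["cut1_date"]) or pd.isna(row["last_cut_date"]):
            reasons.loc[eligible] = "missing_cut_dates"
            continue
        cut2 = None if pd.isna(row["cut2_date"]) else row["cut2_date"].date()
        try:
            cuts = CutSchedule(
                cut1=row["cut1_date"].date(),
                cut2=cut2,
                last_cut=row["last_cut_date"].date(),
            )
            seg = segment_season(
                weather[site], int(row["harvest_year"]), cuts.last_cut
            )
        except ValueError as exc:
            reasons.loc[eligible] = f"unit_error: {exc}"
            continue
        units.append(
            EnvironmentUnit(site, str(row["experiment_id"]),
                            int(row["harvest_year"]), seg, cuts)
        )
    return units, reasons


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if not config.weather_csv or not config.trials_csv:
        raise ValueError("weather_csv and trials_csv are required")
    weather = read_weather_csv(config.weather_csv)
    trials = read_trials_csv(config.trials_csv)

    report = validate_inputs(weather, trials)
    if len(report):
        logger.warning("input validation found %d issues", len(report))
        if config.strict:
            raise ValueError(
                f"strict mode: {len(report)} validation issues\n{report.to_string()}"
            )

    trials, imputation_log = impute_missing_cut_dates(trials)
    units, exclusion = build_environment_units(trials, weather)

    write_segmentation_csv((u.segmentation for u in units), outdir / "segmentation.csv")
    var_table = compute_all_variables(units, weather)
    var_table.to_csv(outdir / "variables.csv", index=False)
    var_table = var_table.copy()
    var_table["unit"] = (
        var_table["site_id"].astype(str)
        + "|" + var_table["harvest_year"].astype(str)
        + "|" + var_table["experiment_id"].astype(str)
    )
    var_table = var_table.set_index("unit")

    eligible = trials[exclusion == ""].copy()
    results_frames, profile_rows, categorized_frames, failures = [], [], [], []
    for species in sorted(eligible["species"].unique()):
        sp_df = eligible[eligible["species"] == species]
        fits, reporting_by_var = {}, {}
        for var_id in config.variables:
            try:
                unit_values = var_table[var_id].astype(float)
                cat_df, _ = attach_categories(sp_df, unit_values, var_id)
                categorized_frames.append(cat_df)
                usable = cat_df["category"].notna()
                _, reporting = select_reporting_set(
                    sp_df, usable=usable,
                    year_range=config.year_range, min_obs=config.min_obs,
                )
                fit = fit_gxe_model(
                    cat_df[usable], species=species, variable_id=var_id,
                    df_method=config.df_method,
                )
                fits[var_id] = fit
                reporting_by_var[var_id] = reporting
                in_range = sp_df["harvest_year"].between(*config.year_range)
                denom = float(
                    sp_df.loc[in_range & sp_df["cultivar"].isin(reporting),
                              "annual_dm_yield_kg_ha"].mean()
                )
                prof = response_profile(fit, reporting, denom)
                prof.insert(0, "species", species)
                prof.insert(1, "variable_id", var_id)
                profile_rows.append(prof)
            except Exception as exc:  # recorded, not silently dropped
                fits[var_id] = exc
                failures.append(
                    {"species": species, "variable_id": var_id, "error": str(exc)}
                )
        summary, n_sig, failed = summarize_species(
            fits, reporting_by_var, config.alpha_e, config.alpha_gxe
        )
        summary["n_significant_gxe"] = n_sig
        results_frames.append(summary)

    results = (
        pd.concat(results_frames, ignore_index=True)
        if results_frames else pd.DataFrame()
    )
    results.to_csv(outdir / "results.csv", index=False)
    profiles = (
        pd.concat(profile_rows, ignore_index=True) if profile_rows else pd.DataFrame()
    )
    profiles.to_csv(outdir / "profiles.csv", index=False)
    categories = (
        pd.concat(categorized_frames, ignore_index=True)
        if categorized_frames else pd.DataFrame()
    )
    categories.to_csv(outdir / "categories.csv", index=False)

    excl_counts = exclusion[exclusion != ""].value_counts().to_dict()
    cfg_dict = dataclasses.asdict(config)
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "versions": {
            "respdiv": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "observations_total": int(len(trials)),
            "observations_eligible": int((exclusion == "").sum()),
            "observations_excluded": {k: int(v) for k, v in excl_counts.items()},
            "environment_units": len(units),
            "imputed_cut_dates": int(len(imputation_log)),
            "validation_issues": int(len(report)),
            "species": int(eligible["species"].nunique()),
            "results_rows": int(len(results)),
            "failed_fits": len(failures),
        },
        "failed_fits": failures,
        "generated_at": dt.datetime.now(dt.timezone.utc).isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (outdir / "validation_report.csv").write_text(report.to_csv(index=False))
    return manifest
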