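"""Seeded generators for weather and trial-yield data with known truth.

The weather generator emulates a northern maritime-continental climate:
a sinusoidal annual temperature cycle with AR(1) day-to-day anomalies
(so winter frost below −10 °C and a spring warm spell above 5 °C both
occur, and the FH/WP/GP segmentation rules trigger), plus Bernoulli–
gamma daily precipitation.  The trial generator runs the analysis model
forward: yields are grand mean + cultivar + category + interaction +
unit random effect + residual, with the category taken from the *true*
tertile of a chosen agroclimatic variable computed from the generated
weather — so the pipeline's own segmentation and categorization are
exercised against known truth.  Every planted effect is returned in a
truth record for recovery tests.
"""

from __future__ import annotations

import datetime as dt
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .weather import WeatherSeries, segment_season
from .variables import CutSchedule, EnvironmentUnit, compute_variable
from .trials import categorize_tertiles

__all__ = [
    "WeatherGenConfig",
    "TrialGenConfig",
    "generate_weather",
    "generate_trials",
    "generate_dataset",
    "simulate_model_dataset",
    "mask_cut_dates",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class WeatherGenConfig:
    """Northern preset by default: mean 3 °C, seasonal amplitude 14 °C."""

    annual_mean_c: float = 3.0
    amplitude_c: float = 14.0
    phase_doy: float = 200.0          # warmest day of year (mid July)
    ar1: float = 0.7
    innovation_sd_c: float = 3.0
    tmin_offset_c: float = 4.0
    tmax_offset_c: float = 4.0
    diurnal_noise_sd_c: float = 1.5
    wet_day_prob: float = 0.45
    precip_shape: float = 0.8
    precip_scale_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_c < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.wet_day_prob <= 1.0:
            raise ValueError("wet-day probability must lie in [0, 1]")
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if self.tmin_offset_c < 0 or self.tmax_offset_c < 0:
            raise ValueError("tmin/tmax offsets must be >= 0")


@dataclass(frozen=True)
class TrialGenConfig:
    """Trial-network generator; defaults mirror a small variety-trial grid.

    The default variance structure (σ_unit = 1000, σ_ε = 400 kg DM ha⁻¹)
    makes the site × year × experiment random effects carry most of the
    total variation, as in real multi-environment forage trials; the
    grand mean of 7000 kg DM ha⁻¹ yr⁻¹ is a typical Nordic forage yield.
    ``interaction_range_kg`` is the planted spread of cultivar responses
    (high-minus-low category contrast): 0 means no G×E.
    """

    n_sites: int = 5
    n_years: int = 2
    n_experiments: int = 3
    n_cultivars: int = 6
    species: str = "timothy"
    grand_mean_kg: float = 7000.0
    cultivar_sd_kg: float = 300.0
    category_effects_kg: tuple[float, float, float] = (-500.0, 0.0, 500.0)
    interaction_range_kg: float = 0.0
    sigma_unit_kg: float = 1000.0
    sigma_eps_kg: float = 400.0
    cut1_doy: int = 165
    cut2_gap_days: int = 45
    cut3_gap_days: int = 40
    cut_jitter_sd_days: float = 4.0
    three_cuts: bool = True
    category_variable: str = "GP_TSUM5"
    year_start: int = 2005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cultivar_sd_kg", "sigma_unit_kg", "sigma_eps_kg",
                     "cut_jitter_sd_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_units(self) -> int:
        return self.n_sites * self.n_years * self.n_experiments


def _site_rng(seed: int, site_id: str, stream: int = 0) -> np.random.Generator:
    # deterministic per-site sub-stream
    return np.random.default_rng([seed, zlib.crc32(site_id.encode()), stream])


def generate_weather(
    config: WeatherGenConfig, site_id: str, years: list[int]
) -> WeatherSeries:
    """Daily series for [1 Jan of min(years), 31 Dec of max(years)]."""
    rng = _site_rng(config.seed, site_id)
    start = dt.date(min(years), 1, 1)
    end = dt.date(max(years), 12, 31)
    idx = pd.date_range(start, end, freq="D")
    doy = idx.dayofyear.to_numpy(float)
    n = len(idx)

    seasonal = config.annual_mean_c + config.amplitude_c * np.cos(
        2 * np.pi * (doy - config.phase_doy) / DAYS_PER_YEAR
    )
    anom = np.empty(n)
    stat_sd = (
        config.innovation_sd_c / np.sqrt(1 - config.ar1**2)
        if config.innovation_sd_c > 0
        else 0.0
    )
    anom[0] = rng.normal(0.0, stat_sd) if stat_sd > 0 else 0.0
    innov = rng.normal(0.0, config.innovation_sd_c, n) if config.innovation_sd_c > 0 else np.zeros(n)
    for t in range(1, n):
        anom[t] = config.ar1 * anom[t - 1] + innov[t]
    tmean = seasonal + anom

    half_lo = np.abs(rng.normal(0.0, config.diurnal_noise_sd_c, n))
    half_hi = np.abs(rng.normal(0.0, config.diurnal_noise_sd_c, n))
    tmin = tmean - config.tmin_offset_c - half_lo
    tmax = tmean + config.tmax_offset_c + half_hi

    wet = rng.random(n) < config.wet_day_prob
    precip = np.where(
        wet, rng.gamma(config.precip_shape, config.precip_scale_mm, n), 0.0
    )

    frame = pd.DataFrame(
        {"tmean": tmean, "tmin": tmin, "tmax": tmax, "precip": precip}, index=idx
    )
    return WeatherSeries(site_id, frame)


def _planted_responses(n_cultivars: int, interaction_range: float) -> np.ndarray:
    """Evenly spread cultivar responses summing the range, centered at 0."""
    if n_cultivars == 1:
        return np.zeros(1)
    return np.linspace(-interaction_range / 2.0, interaction_range / 2.0, n_cultivars)


def _interaction_matrix(responses: np.ndarray) -> np.ndarray:
    """γ_ic with high − low = response_i and zero row/column means."""
    gamma = np.zeros((len(responses), 3))
    gamma[:, 0] = -responses / 2.0  # low
    gamma[:, 2] = responses / 2.0   # high
    return gamma


def generate_trials(
    config: TrialGenConfig, weather: dict[str, WeatherSeries]
) -> tuple[pd.DataFrame, dict]:
    """Trial observations for every site × year × experiment unit.

    Each unit carries a full cut schedule drawn from the DOY rules, is
    segmented against its site's weather, and is assigned the tertile of
    ``config.category_variable`` across all units; yields then follow
    the forward model.  Raises when fewer than three units have a
    computable category variable.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 2])
    cultivars = [f"cv{i + 1:02d}" for i in range(cfg.n_cultivars)]
    cultivar_effects = rng.normal(0.0, cfg.cultivar_sd_kg, cfg.n_cultivars)
    cultivar_effects -= cultivar_effects.mean() if cfg.n_cultivars else 0.0
    responses = _planted_responses(cfg.n_cultivars, cfg.interaction_range_kg)
    gamma = _interaction_matrix(responses)

    sites = sorted(weather)
    if len(sites) < cfg.n_sites:
        raise ValueError(f"need weather for {cfg.n_sites} sites, have {len(sites)}")
    sites = sites[: cfg.n_sites]
    years = [cfg.year_start + j for j in range(cfg.n_years)]

    units, unit_values, unit_ids = [], {}, []
    for site in sites:
        series = weather[site]
        for year in years:
            for e in range(cfg.n_experiments):
                exp_id = f"exp{e + 1}"
                jit = rng.normal(0.0, cfg.cut_jitter_sd_days, 3)
                cut1 = dt.date(year, 1, 1) + dt.timedelta(
                    days=cfg.cut1_doy - 1 + int(round(jit[0]))
                )
                cut2 = cut1 + dt.timedelta(days=cfg.cut2_gap_days + int(round(jit[1])))
                if cfg.three_cuts:
                    last = cut2 + dt.timedelta(
                        days=cfg.cut3_gap_days + int(round(jit[2]))
                    )
                    cuts = CutSchedule(cut1=cut1, cut2=cut2, last_cut=last)
                else:
                    cuts = CutSchedule(cut1=cut1, cut2=cut2, last_cut=cut2)
                seg = segment_season(series, year, cuts.last_cut)
                unit = EnvironmentUnit(site, exp_id, year, seg, cuts)
                uid = f"{site}|{year}|{exp_id}"
                res = compute_variable(unit, series, cfg.category_variable)
                units.append(unit)
                unit_ids.append(uid)
                unit_values[uid] = np.nan if res.value is None else res.value

    values = pd.Series(unit_values)
    usable = values.dropna()
    if len(usable) < 3:
        raise ValueError(
            f"only {len(usable)} units have a computable "
            f"{cfg.category_variable}; cannot form tertiles"
        )
    counts = pd.Series(cfg.n_cultivars, index=usable.index)
    labels, breakpoints = categorize_tertiles(usable, counts)
    cat_index = {"low": 0, "moderate": 1, "high": 2}

    unit_effects = {uid: rng.normal(0.0, cfg.sigma_unit_kg) for uid in unit_ids}
    rows = []
    for unit, uid in zip(units, unit_ids):
        label = labels.get(uid)
        cat_eff = 0.0 if label is None else cfg.category_effects_kg[cat_index[label]]
        for i, cv in enumerate(cultivars):
            inter = 0.0 if label is None else gamma[i, cat_index[label]]
            y = (
                cfg.grand_mean_kg
                + cultivar_effects[i]
                + cat_eff
                + inter
                + unit_effects[uid]
                + rng.normal(0.0, cfg.sigma_eps_kg)
            )
            rows.append(
                {
                    "site_id": unit.site_id,
                    "experiment_id": unit.experiment_id,
                    "harvest_year": unit.harvest_year,
                    "species": cfg.species,
                    "cultivar": cv,
                    "origin": "domestic",
                    "annual_dm_yield_kg_ha": y,
                    "cut1_date": pd.Timestamp(unit.cuts.cut1),
                    "cut2_date": pd.Timestamp(unit.cuts.cut2) if unit.cuts.cut2 else pd.NaT,
                    "last_cut_date": pd.Timestamp(unit.cuts.last_cut),
                }
            )

    truth = {
        "config": asdict(cfg),
        "cultivars": cultivars,
        "cultivar_effects": dict(zip(cultivars, cultivar_effects.tolist())),
        "responses_high_minus_low": dict(zip(cultivars, responses.tolist())),
        "interaction_range": float(responses.max() - responses.min()),
        "category_effects": list(cfg.category_effects_kg),
        "unit_effects": unit_effects,
        "unit_values": {k: float(v) for k, v in values.items() if np.isfinite(v)},
        "unit_categories": {k: v for k, v in labels.dropna().items()},
        "breakpoints": list(breakpoints),
    }
    return pd.DataFrame(rows), truth


def generate_dataset(
    trial_config: TrialGenConfig, weather_config: WeatherGenConfig | None = None
) -> tuple[pd.DataFrame, dict[str, WeatherSeries], dict]:
    """Convenience wrapper: weather for all sites/years, then trials.

    Weather starts the year before the first harvest year so the fall
    hardening of the first season is observable.
    """
    wcfg = weather_config or WeatherGenConfig(seed=trial_config.seed)
    years = list(
        range(trial_config.year_start - 1, trial_config.year_start + trial_config.n_years)
    )
    weather = {
        f"site{i + 1:02d}": generate_weather(wcfg, f"site{i + 1:02d}", years)
        for i in range(trial_config.n_sites)
    }
    df, truth = generate_trials(trial_config, weather)
    return df, weather, truth


def simulate_model_dataset(
    n_cultivars: int = 6,
    n_units: int = 30,
    grand_mean: float = 7000.0,
    cultivar_sd: float = 300.0,
    category_effects: tuple[float, float, float] = (-500.0, 0.0, 500.0),
    interaction_range: float = 0.0,
    sigma_unit: float = 1000.0,
    sigma_eps: float = 400.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Model-forward dataset with categories assigned directly.

    Units are split equally over the three categories (``n_units`` must
    be divisible by 3) and every unit observes every cultivar.  This is
    the weather-free twin of :func:`generate_trials` for calibration and
    power studies where the environmental pathway is not under test.
    """
    if n_units % 3:
        raise ValueError("n_units must be divisible by 3")
    rng = rng if rng is not None else np.random.default_rng()
    cultivars = [f"cv{i + 1:02d}" for i in range(n_cultivars)]
    cats = ["low", "moderate", "high"]
    cult_eff = rng.normal(0.0, cultivar_sd, n_cultivars)
    cult_eff -= cult_eff.mean()
    responses = _planted_responses(n_cultivars, interaction_range)
    gamma = _interaction_matrix(responses)
    rows = []
    unit_effects = {}
    for u in range(n_units):
        cat = cats[u % 3]
        uid = f"u{u + 1:03d}"
        ue = rng.normal(0.0, sigma_unit)
        unit_effects[uid] = ue
        ci = cats.index(cat)
        for i, cv in enumerate(cultivars):
            y = (
                grand_mean + cult_eff[i] + category_effects[ci] + gamma[i, ci]
                + ue + rng.normal(0.0, sigma_eps)
            )
            rows.append(
                {"unit": uid, "category": cat, "cultivar": cv,
                 "annual_dm_yield_kg_ha": y}
            )
    truth = {
        "cultivar_effects": dict(zip(cultivars, cult_eff.tolist())),
        "responses_high_minus_low": dict(zip(cultivars, responses.tolist())),
        "interaction_range": float(responses.max() - responses.min()),
        "category_effects": list(category_effects),
        "unit_effects": unit_effects,
    }
    return pd.DataFrame(rows), truth


def mask_cut_dates(
    df: pd.DataFrame,
    fraction: float,
    seed: int,
    max_redraws: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank a random fraction of cut-date fields, reproducibly.

    Re-draws the mask (up to ``max_redraws`` times) if it would leave
    some site-year with no observed dates at all, which would make the
    masked trials unimputable.  Returns the masked frame and a truth
    table of the original values.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    slots = ["cut1_date", "cut2_date", "last_cut_date"]
    cells = [
        (idx, slot) for slot in slots for idx in df.index[df[slot].notna()]
    ]
    n_mask = int(round(fraction * len(cells)))
    if n_mask == 0:
        return df.copy(), pd.DataFrame(columns=["obs_index", "field", "true_date"])

    site_year = df["site_id"].astype(str) + "|" + df["harvest_year"].astype(str)
    for attempt in range(max_redraws):
        rng = np.random.default_rng([seed, attempt])
        chosen = [cells[i] for i in rng.choice(len(cells), n_mask, replace=False)]
        masked_per_sy: dict[str, int] = {}
        for idx, _ in chosen:
            masked_per_sy[site_year[idx]] = masked_per_sy.get(site_year[idx], 0) + 1
        total_per_sy = site_year.map(site_year.value_counts()) * len(slots)
        ok = all(
            masked_per_sy[sy] < int(total_per_sy[df.index[site_year == sy][0]])
            for sy in masked_per_sy
        )
        if ok:
            break
    else:
        raise ValueError("could not draw a mask keeping every site-year imputable")

    out = df.copy()
    log = []
    for idx, slot in chosen:
        log.append(
            {"obs_index": idx, "field": slot, "true_date": out.at[idx, slot]}
        )
        out.at[idx, slot] = pd.NaT
    return out, pd.DataFrame(log)
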