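"""Synthetic monitor network and smoke-injection generator.

Emulates the statistical structure the burden pipeline assumes for a
temperate, wood-heating region in the southern hemisphere:

* hourly PM2.5 at monitoring stations = constant regional background
  + a wood-heater smoke (WHS) term, active through winter (May-Aug) and
    stochastically on cold transition-month days, scaled by heating degree
    days and shaped by a bimodal diurnal profile (large overnight peak,
    smaller early-morning peak);
* sporadic multi-day landscape-fire smoke (LFS) events with heavy-tailed
  magnitudes, mostly in summer (Nov-Feb) and on warm transition-month days;
* daily min/max temperatures from a seasonal sinusoid plus shared weather
  noise, so heating degree days emerge from the temperature series rather
  than being generated directly;
* point-located statistical areas with populations of 3,000-25,000 persons
  and age-band breakdowns, each with a PM monitor within a few km of the
  centroid.

Every area-day carries a ground-truth source label (unpolluted / WHS / LFS)
and the true source-attributable PM2.5 (the injected smoke term, exactly),
so downstream estimates can be scored against truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeneratorConfig",
    "SyntheticWorld",
    "default_diurnal_profile",
    "generate_world",
    "write_world",
    "read_world",
]

WINTER_MONTHS = (5, 6, 7, 8)
SUMMER_MONTHS = (11, 12, 1, 2)
TRANSITION_MONTHS = (3, 4, 9, 10)

#: heating degree days at which the WHS amplitude equals its nominal value
HDD_REFERENCE = 10.0
#: floor applied to hourly concentrations so every hour stays a valid (>0) reading
PM_FLOOR = 0.05

# synthetic state-wide baseline incidence rates, cases per person-year;
# magnitudes chosen to be realistic for an Australian state population
DEFAULT_BASELINE_RATES = [
    ("all_cause_mortality", "30+", 0.012),
    ("all_cause_mortality", "all", 0.0075),
    ("cvd_admission", "all", 0.022),
    ("rsp_admission", "all", 0.020),
    ("asthma_ed", "0-17", 0.006),
    ("asthma_ed", "18-64", 0.002),
    ("asthma_ed", "64+", 0.003),
]


def default_diurnal_profile() -> np.ndarray:
    """Bimodal 24-hour WHS weight vector, normalised to mean 1.

    Large overnight peak (heaters banked down through the evening and
    night-time inversions trapping smoke) centred near 23:00, smaller
    early-morning peak near 07:00.
    """
    hours = np.arange(24.0)
    # circular distance from peak centres
    d_night = np.minimum(np.abs(hours - 23.0), 24.0 - np.abs(hours - 23.0))
    d_morn = np.minimum(np.abs(hours - 7.0), 24.0 - np.abs(hours - 7.0))
    profile = 0.25 + 2.2 * np.exp(-0.5 * (d_night / 2.5) ** 2)
    profile += 0.9 * np.exp(-0.5 * (d_morn / 1.5) ** 2)
    return profile / profile.mean()


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic world; all magnitudes in the units noted."""

    n_areas: int = 20
    n_pm_stations: int = 20
    n_met_stations: int = 20
    start: str = "2015-01-01"
    end: str = "2017-12-31"
    background_mean: float = 1.4  # ug/m3, non-biomass ambient level
    whs_winter_amplitude: float = 6.0  # ug/m3 daily-mean WHS at HDD_REFERENCE
    whs_diurnal_profile: tuple = tuple(default_diurnal_profile())
    whs_day_sigma: float = 0.35  # lognormal sigma of day-to-day WHS variation
    lfs_event_rate: float = 1.5  # events per summer season per area
    lfs_event_magnitude: float = 50.0  # ug/m3, lognormal median of event daily mean
    lfs_magnitude_sigma: float = 0.7  # heavy tail: maxima can reach hundreds
    temp_annual_mean: float = 12.0  # degC
    temp_annual_amplitude: float = 5.0  # degC (summer high / winter low swing)
    temp_daily_range: float = 8.0  # degC between tmin and tmax
    noise_sd: float = 0.3  # ug/m3, hourly instrument/ambient noise
    missing_hour_rate: float = 0.01  # fraction of hourly records dropped
    population_range: tuple = (3000, 25000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_areas < 1 or self.n_pm_stations < 1 or self.n_met_stations < 1:
            raise ValueError("need at least one area, PM station and met station")
        if pd.Timestamp(self.start) > pd.Timestamp(self.end):
            raise ValueError(f"inconsistent date range {self.start}..{self.end}")
        for name in (
            "background_mean",
            "whs_winter_amplitude",
            "lfs_event_rate",
            "lfs_event_magnitude",
            "noise_sd",
            "temp_daily_range",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.population_range
        if not (0 < lo <= hi):
            raise ValueError("population_range must be positive and ordered")
        if len(self.whs_diurnal_profile) != 24 or min(self.whs_diurnal_profile) < 0:
            raise ValueError("whs_diurnal_profile must be 24 nonnegative weights")


@dataclass
class SyntheticWorld:
    """A generated study region with ground truth.

    All tables are tidy pandas DataFrames; ``truth`` has one row per
    area-day with the true source label and true attributable PM2.5.
    """

    config: GeneratorConfig
    areas: pd.DataFrame  # area_id, region_id, x_km, y_km, pop_*, woodstoves
    pm_stations: pd.DataFrame  # station_id, area_id, x_km, y_km
    met_stations: pd.DataFrame  # station_id, area_id, x_km, y_km
    hourly_pm: pd.DataFrame  # station_id, timestamp, pm25
    daily_met: pd.DataFrame  # station_id, date, tmin, tmax
    truth: pd.DataFrame  # area_id, date, day_type, pm25_attributable
    baseline_rates: pd.DataFrame  # outcome, age_group, incidence_rate

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.config.start, self.config.end, freq="D")


def _layout_areas(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Jittered grid of area centroids over a ~200 km domain, 4 regions."""
    n = cfg.n_areas
    ncol = int(np.ceil(np.sqrt(n)))
    idx = np.arange(n)
    gx = (idx % ncol).astype(float)
    gy = (idx // ncol).astype(float)
    spacing = 40.0  # km between neighbouring centroids
    x = gx * spacing + rng.uniform(-6, 6, n)
    y = gy * spacing + rng.uniform(-6, 6, n)

    lo, hi = cfg.population_range
    # right-skewed populations with a median near 10k, clipped to the range
    pop = np.clip(rng.lognormal(np.log(9500), 0.45, n), lo, hi).round().astype(int)
    # age-band shares with mild per-area jitter
    share_0_17 = np.clip(rng.normal(0.22, 0.02, n), 0.15, 0.30)
    share_64p = np.clip(rng.normal(0.18, 0.02, n), 0.10, 0.28)
    share_18_64 = 1.0 - share_0_17 - share_64p
    share_30p = np.clip(rng.normal(0.58, 0.02, n), 0.45, 0.70)

    xm, ym = np.median(x), np.median(y)
    region = np.where(x <= xm, np.where(y <= ym, "R1", "R2"), np.where(y <= ym, "R3", "R4"))

    return pd.DataFrame(
        {
            "area_id": [f"A{i:03d}" for i in range(n)],
            "region_id": region,
            "x_km": x,
            "y_km": y,
            "pop_total": pop,
            "pop_0_17": (pop * share_0_17).round().astype(int),
            "pop_18_64": (pop * share_18_64).round().astype(int),
            "pop_64plus": (pop * share_64p).round().astype(int),
            "pop_30plus": (pop * share_30p).round().astype(int),
            "woodstoves": (pop / 7.5).round().astype(int),
        }
    )


def _layout_stations(
    prefix: str, n_stations: int, areas: pd.DataFrame, rng: np.random.Generator, max_offset_km: float
) -> pd.DataFrame:
    """Assign stations round-robin to areas, each close to its area centroid."""
    rows = []
    for s in range(n_stations):
        a = areas.iloc[s % len(areas)]
        r = rng.uniform(0.5, max_offset_km)
        theta = rng.uniform(0, 2 * np.pi)
        rows.append(
            {
                "station_id": f"{prefix}{s:03d}",
                "area_id": a["area_id"],
                "x_km": a["x_km"] + r * np.cos(theta),
                "y_km": a["y_km"] + r * np.sin(theta),
            }
        )
    return pd.DataFrame(rows)


def _daily_mean_temperature(
    cfg: GeneratorConfig, dates: pd.DatetimeIndex, areas: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """(n_days, n_areas) daily mean temperature: sinusoid + shared weather noise.

    Southern hemisphere phasing: warmest in mid-January, coldest mid-July.
    Weather noise is shared across the domain (one synoptic system) with a
    small per-area perturbation, so degree days are spatially smooth.
    """
    doy = dates.dayofyear.to_numpy()
    seasonal = cfg.temp_annual_mean + cfg.temp_annual_amplitude * np.cos(
        2 * np.pi * (doy - 15) / 365.25
    )
    weather = rng.normal(0.0, 2.0, len(dates))
    # cooler areas toward the high-latitude (southern) edge of the domain
    area_offset = -1.0 * (areas["y_km"].to_numpy() - areas["y_km"].mean()) / 100.0
    local = rng.normal(0.0, 0.5, (len(dates), len(areas)))
    return (seasonal + weather)[:, None] + area_offset[None, :] + local


def _whs_daily(
    cfg: GeneratorConfig,
    dates: pd.DatetimeIndex,
    hdd: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_days, n_areas) daily-mean WHS-attributable PM2.5."""
    months = dates.month.to_numpy()
    n_days, n_areas = hdd.shape
    winter = np.isin(months, WINTER_MONTHS)[:, None]
    transition = np.isin(months, TRANSITION_MONTHS)[:, None]
    # on cold transition days heaters come on; probability rises with HDD
    p_on = 1.0 / (1.0 + np.exp(-(hdd - 8.0) / 1.5))
    active = winter | (transition & (rng.uniform(size=hdd.shape) < p_on))
    day_factor = rng.lognormal(0.0, cfg.whs_day_sigma, hdd.shape)
    whs = cfg.whs_winter_amplitude * (hdd / HDD_REFERENCE) * day_factor
    return np.where(active & (hdd > 0), whs, 0.0)


def _lfs_daily(
    cfg: GeneratorConfig,
    dates: pd.DatetimeIndex,
    hdd: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_days, n_areas) daily-mean LFS-attributable PM2.5.

    Multi-day events: Poisson count per area per summer season (and at half
    the rate across each year's transition days, gated to warm days), start
    date uniform in the season, duration 1-16 days skewed short, event
    magnitude lognormal (heavy-tailed) with +/-40% day-to-day variation.
    """
    months = dates.month.to_numpy()
    years = dates.year.to_numpy()
    n_days, n_areas = hdd.shape
    lfs = np.zeros((n_days, n_areas))

    summer = np.isin(months, SUMMER_MONTHS)
    transition = np.isin(months, TRANSITION_MONTHS)
    # summer seasons span the new year: season key = year of the November
    season_key = np.where(months >= 11, years, years - 1)

    def inject(day_pool: np.ndarray, area: int, rate: float, max_dur: int) -> None:
        if len(day_pool) == 0 or rate <= 0:
            return
        for _ in range(rng.poisson(rate)):
            start = int(rng.choice(day_pool))
            dur = min(1 + rng.geometric(0.4), max_dur)
            mag = rng.lognormal(np.log(cfg.lfs_event_magnitude), cfg.lfs_magnitude_sigma)
            for d in range(start, min(start + dur, n_days)):
                lfs[d, area] += mag * rng.uniform(0.8, 1.2)

    for area in range(n_areas):
        for key in np.unique(season_key[summer]):
            pool = np.flatnonzero(summer & (season_key == key))
            inject(pool, area, cfg.lfs_event_rate, max_dur=16)
        for yr in np.unique(years):
            # prescribed burns happen on warm (low heating demand) days
            pool = np.flatnonzero(transition & (years == yr) & (hdd[:, area] < 8.0))
            inject(pool, area, cfg.lfs_event_rate / 2.0, max_dur=5)
    return lfs


def generate_world(config: GeneratorConfig) -> SyntheticWorld:
    """Generate a complete synthetic world; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(config.start, config.end, freq="D")

    areas = _layout_areas(config, rng)
    pm_stations = _layout_stations("PM", config.n_pm_stations, areas, rng, max_offset_km=3.0)
    met_stations = _layout_stations("MET", config.n_met_stations, areas, rng, max_offset_km=10.0)

    tmean = _daily_mean_temperature(config, dates, areas, rng)  # (days, areas)
    hdd = np.maximum(0.0, 18.0 - tmean)
    whs = _whs_daily(config, dates, hdd, rng)
    lfs = _lfs_daily(config, dates, hdd, rng)

    # ground truth: attributable = injected smoke, label = dominant source
    total_smoke = whs + lfs
    label = np.where(total_smoke <= 0, "unpolluted", np.where(whs >= lfs, "WHS", "LFS"))
    n_days, n_areas = hdd.shape
    truth = pd.DataFrame(
        {
            "area_id": np.repeat(areas["area_id"].to_numpy(), n_days),
            "date": np.tile(dates.to_numpy(), n_areas),
            "day_type": label.T.ravel(),
            "pm25_attributable": total_smoke.T.ravel(),
        }
    )

    # daily met records at stations: area series +/- half the diurnal range + noise
    met_area_idx = areas.set_index("area_id").index.get_indexer(met_stations["area_id"])
    met_frames = []
    for s, ai in zip(met_stations["station_id"], met_area_idx):
        base = tmean[:, ai] + rng.normal(0.0, 0.3, n_days)
        met_frames.append(
            pd.DataFrame(
                {
                    "station_id": s,
                    "date": dates,
                    "tmin": base - config.temp_daily_range / 2.0,
                    "tmax": base + config.temp_daily_range / 2.0,
                }
            )
        )
    daily_met = pd.concat(met_frames, ignore_index=True)

    # hourly PM at stations: background + area smoke shaped over the day + noise
    profile = np.asarray(config.whs_diurnal_profile, dtype=float)
    profile = profile / profile.mean()
    pm_area_idx = areas.set_index("area_id").index.get_indexer(pm_stations["area_id"])
    hours = pd.date_range(
        dates[0], dates[-1] + pd.Timedelta(hours=23), freq="h"
    )
    pm_frames = []
    for s, ai in zip(pm_stations["station_id"], pm_area_idx):
        whs_hourly = np.repeat(whs[:, ai], 24) * np.tile(profile, n_days)
        lfs_hourly = np.repeat(lfs[:, ai], 24)  # fire smoke has no heater diurnality
        pm = config.background_mean + whs_hourly + lfs_hourly
        pm = pm + rng.normal(0.0, config.noise_sd, pm.shape)
        pm = np.maximum(pm, PM_FLOOR)
        keep = rng.uniform(size=pm.shape) >= config.missing_hour_rate
        pm_frames.append(
            pd.DataFrame({"station_id": s, "timestamp": hours[keep], "pm25": pm[keep]})
        )
    hourly_pm = pd.concat(pm_frames, ignore_index=True)

    baseline_rates = pd.DataFrame(
        DEFAULT_BASELINE_RATES, columns=["outcome", "age_group", "incidence_rate"]
    )

    return SyntheticWorld(
        config=config,
        areas=areas,
        pm_stations=pm_stations,
        met_stations=met_stations,
        hourly_pm=hourly_pm,
        daily_met=daily_met,
        truth=truth,
        baseline_rates=baseline_rates,
    )


# ---------------------------------------------------------------------------
# serialisation: the exact CSV/GeoJSON dialects the pipeline consumes
# ---------------------------------------------------------------------------

def _areas_to_geojson(areas: pd.DataFrame) -> dict:
    features = []
    for _, row in areas.iterrows():
        props = row.drop(["x_km", "y_km"]).to_dict()
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row["x_km"], row["y_km"]]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def _areas_from_geojson(obj: dict) -> pd.DataFrame:
    rows = []
    for feat in obj["features"]:
        row = dict(feat["properties"])
        row["x_km"], row["y_km"] = feat["geometry"]["coordinates"]
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = ["area_id", "region_id", "x_km", "y_km"] + [
        c for c in df.columns if c not in ("area_id", "region_id", "x_km", "y_km")
    ]
    return df[cols]


def write_world(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Write the world as the file set consumed by the pipeline; round-trips losslessly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "hourly_pm25": directory / "hourly_pm25.csv",
        "daily_met": directory / "daily_met.csv",
        "areas": directory / "areas.geojson",
        "baseline_rates": directory / "baseline_rates.csv",
        "truth": directory / "truth.csv",
        "stations": directory / "stations.csv",
        "config": directory / "generator_config.yaml",
    }
    hourly = world.hourly_pm.copy()
    hourly["timestamp"] = pd.to_datetime(hourly["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    hourly.to_csv(paths["hourly_pm25"], index=False, float_format="%.17g")

    met = world.daily_met.copy()
    met["date"] = pd.to_datetime(met["date"]).dt.strftime("%Y-%m-%d")
    met.to_csv(paths["daily_met"], index=False, float_format="%.17g")

    paths["areas"].write_text(json.dumps(_areas_to_geojson(world.areas), indent=1))
    world.baseline_rates.to_csv(paths["baseline_rates"], index=False, float_format="%.17g")

    truth = world.truth.copy()
    truth["date"] = pd.to_datetime(truth["date"]).dt.strftime("%Y-%m-%d")
    truth.to_csv(paths["truth"], index=False, float_format="%.17g")

    stations = pd.concat(
        [world.pm_stations.assign(kind="pm"), world.met_stations.assign(kind="met")],
        ignore_index=True,
    )
    stations.to_csv(paths["stations"], index=False, float_format="%.17g")

    cfg = dataclasses.asdict(world.config)
    cfg["whs_diurnal_profile"] = [float(v) for v in cfg["whs_diurnal_profile"]]
    cfg["population_range"] = [int(v) for v in cfg["population_range"]]
    paths["config"].write_text(yaml.safe_dump(cfg))
    return paths


def read_world(directory: str | Path) -> SyntheticWorld:
    """Read back a world written by :func:`write_world`."""
    directory = Path(directory)
    cfg_raw = yaml.safe_load((directory / "generator_config.yaml").read_text())
    cfg_raw["whs_diurnal_profile"] = tuple(cfg_raw["whs_diurnal_profile"])
    cfg_raw["population_range"] = tuple(cfg_raw["population_range"])
    config = GeneratorConfig(**cfg_raw)

    hourly = pd.read_csv(directory / "hourly_pm25.csv", parse_dates=["timestamp"])
    met = pd.read_csv(directory / "daily_met.csv", parse_dates=["date"])
    areas = _areas_from_geojson(json.loads((directory / "areas.geojson").read_text()))
    rates = pd.read_csv(directory / "baseline_rates.csv")
    truth = pd.read_csv(directory / "truth.csv", parse_dates=["date"])
    stations = pd.read_csv(directory / "stations.csv")
    pm_st = stations[stations["kind"] == "pm"].drop(columns="kind").reset_index(drop=True)
    met_st = stations[stations["kind"] == "met"].drop(columns="kind").reset_index(drop=True)
    return SyntheticWorld(
        config=config,
        areas=areas,
        pm_stations=pm_st,
        met_stations=met_st,
        hourly_pm=hourly,
        daily_met=met,
        truth=truth,
        baseline_rates=rates,
    )
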