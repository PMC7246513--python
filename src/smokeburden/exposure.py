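"""Exposure surface: station records -> daily means -> area-level fields.

Hourly PM2.5 records are collapsed to daily station means subject to a
validity rule (a daily mean exists only when at least 18 hourly readings
strictly greater than zero are available). Heating degree days (HDD) are
computed at meteorological stations as max(0, 18 degC - daily mean
temperature) and, like the other daily fields, interpolated to each
statistical-area centroid by inverse distance weighting (IDW) restricted
to stations within a fixed radius (default 100 km).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "MIN_VALID_HOURS",
    "daily_mean",
    "daily_station_series",
    "heating_degree_days",
    "met_daily_series",
    "idw_interpolate",
    "build_area_days",
]

logger = logging.getLogger("smokeburden")

MIN_VALID_HOURS = 18
DEFAULT_RADIUS_KM = 100.0
DEFAULT_IDW_POWER = 2.0
#: stations closer than this to a target are treated as coincident (~1 m)
COINCIDENT_EPS_KM = 1e-3
COMFORT_TEMP_C = 18.0


def daily_mean(pm25_hours: np.ndarray | list) -> float:
    """Daily mean of hourly PM2.5, or NaN if fewer than 18 valid hours.

    An hour is valid when its reading is finite and strictly greater than
    zero; zero readings count as invalid instrument hours.
    """
    v = np.asarray(pm25_hours, dtype=float)
    valid = v[np.isfinite(v) & (v > 0)]
    if valid.size < MIN_VALID_HOURS:
        return float("nan")
    return float(valid.mean())


def daily_station_series(hourly: pd.DataFrame) -> pd.DataFrame:
    """Collapse hourly records to one row per station-day.

    Parameters
    ----------
    hourly : DataFrame with columns station_id, timestamp, pm25.

    Returns
    -------
    DataFrame with station_id, date, pm25_mean (NaN when invalid),
    n_valid_hours.
    """
    df = hourly[["station_id", "timestamp", "pm25"]].copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    valid = np.isfinite(df["pm25"]) & (df["pm25"] > 0)
    df["valid_sum"] = np.where(valid, df["pm25"], 0.0)
    df["n_valid_hours"] = valid.astype(int)
    out = (
        df.groupby(["station_id", "date"], sort=True)[["valid_sum", "n_valid_hours"]]
        .sum()
        .reset_index()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pm25_mean"] = np.where(
            out["n_valid_hours"] >= MIN_VALID_HOURS,
            out["valid_sum"] / out["n_valid_hours"],
            np.nan,
        )
    return out[["station_id", "date", "pm25_mean", "n_valid_hours"]]


def heating_degree_days(tmin, tmax, comfort: float = COMFORT_TEMP_C):
    """Degrees Celsius by which the daily mean temperature falls short of comfort.

    HDD = max(0, comfort - (tmin + tmax) / 2). Accepts scalars or arrays.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax):
        raise ValueError("tmin exceeds tmax")
    hdd = np.maximum(0.0, comfort - (tmin + tmax) / 2.0)
    return float(hdd) if hdd.ndim == 0 else hdd


def met_daily_series(daily_met: pd.DataFrame, comfort: float = COMFORT_TEMP_C) -> pd.DataFrame:
    """Attach HDD to a daily met-station table (station_id, date, tmin, tmax)."""
    out = daily_met.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.normalize()
    out["hdd"] = heating_degree_days(out["tmin"].to_numpy(), out["tmax"].to_numpy(), comfort)
    return out


def idw_interpolate(
    station_values,
    target,
    radius: float = DEFAULT_RADIUS_KM,
    power: float = DEFAULT_IDW_POWER,
) -> float:
    """Inverse-distance-weighted value at ``target``.

    ``station_values`` is a sequence of ((x, y), value) pairs. Stations
    beyond ``radius`` or with missing values are ignored; a station
    coincident with the target (within ~1 m) short-circuits to its value.
    Returns NaN when no station qualifies.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    target = np.asarray(target, dtype=float)
    num = den = 0.0
    for coords, value in station_values:
        if value is None or not np.isfinite(value):
            continue
        d = float(np.hypot(*(np.asarray(coords, dtype=float) - target)))
        if d > radius:
            continue
        if d < COINCIDENT_EPS_KM:
            return float(value)
        w = d ** (-power)
        num += w * value
        den += w
    return num / den if den > 0 else float("nan")


def _idw_matrix(
    values: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised IDW over a (days x stations) value matrix.

    ``weights`` is (areas x stations), zero outside the radius. Missing
    station-days are excluded day by day and the remaining weights
    renormalised. Returns (days x areas) interpolated values and the
    per-day contributing-station counts.
    """
    mask = np.isfinite(values)
    v0 = np.where(mask, values, 0.0)
    num = v0 @ weights.T  # (days, areas)
    den = mask.astype(float) @ weights.T
    with np.errstate(invalid="ignore", divide="ignore"):
        interp = np.where(den > 0, num / den, np.nan)
    n_contrib = mask.astype(int) @ (weights > 0).T.astype(int)
    return interp, n_contrib


def _weights(
    targets_xy: np.ndarray, stations_xy: np.ndarray, radius: float, power: float
) -> np.ndarray:
    d = cdist(targets_xy, stations_xy)
    d = np.maximum(d, COINCIDENT_EPS_KM)  # coincident stations dominate finitely
    w = np.where(d <= radius, d ** (-power), 0.0)
    return w


def build_area_days(
    daily_pm: pd.DataFrame,
    daily_met: pd.DataFrame,
    areas: pd.DataFrame,
    pm_stations: pd.DataFrame,
    met_stations: pd.DataFrame,
    radius: float = DEFAULT_RADIUS_KM,
    power: float = DEFAULT_IDW_POWER,
) -> pd.DataFrame:
    """Interpolate daily PM2.5, HDD, tmin and tmax to every area centroid.

    Parameters
    ----------
    daily_pm : output of :func:`daily_station_series`.
    daily_met : output of :func:`met_daily_series` (must carry hdd).
    areas : table with area_id, x_km, y_km.
    pm_stations, met_stations : tables with station_id, x_km, y_km.

    Returns one row per area x date; pm25 is NaN where no valid station
    lies within the radius (such area-days are excluded downstream).
    """
    if len(areas) == 0 or len(pm_stations) == 0 or len(met_stations) == 0:
        raise ValueError("areas and station tables must be nonempty")

    targets = areas[["x_km", "y_km"]].to_numpy(dtype=float)

    pm_wide = daily_pm.pivot(index="date", columns="station_id", values="pm25_mean")
    pm_xy = (
        pm_stations.set_index("station_id")
        .loc[pm_wide.columns, ["x_km", "y_km"]]
        .to_numpy(dtype=float)
    )
    w_pm = _weights(targets, pm_xy, radius, power)
    pm_interp, n_contrib = _idw_matrix(pm_wide.to_numpy(dtype=float), w_pm)

    met = met_daily_series(daily_met) if "hdd" not in daily_met.columns else daily_met
    met_fields = {}
    met_xy = None
    for fld in ("hdd", "tmin", "tmax"):
        wide = met.pivot(index="date", columns="station_id", values=fld)
        if met_xy is None:
            met_xy = (
                met_stations.set_index("station_id")
                .loc[wide.columns, ["x_km", "y_km"]]
                .to_numpy(dtype=float)
            )
            w_met = _weights(targets, met_xy, radius, power)
        met_fields[fld], _ = _idw_matrix(wide.to_numpy(dtype=float), w_met)
        met_index = wide.index

    dates = pm_wide.index
    if not met_index.equals(dates):
        # align met fields onto the PM date axis
        aligned = {}
        for fld, arr in met_fields.items():
            df = pd.DataFrame(arr, index=met_index).reindex(dates)
            aligned[fld] = df.to_numpy()
        met_fields = aligned

    n_areas = len(areas)
    n_days = len(dates)
    out = pd.DataFrame(
        {
            "area_id": np.repeat(areas["area_id"].to_numpy(), n_days),
            "date": np.tile(dates.to_numpy(), n_areas),
            "pm25": pm_interp.T.ravel(),
            "hdd": met_fields["hdd"].T.ravel(),
            "tmin": met_fields["tmin"].T.ravel(),
            "tmax": met_fields["tmax"].T.ravel(),
            "n_contributing_stations": n_contrib.T.ravel(),
        }
    )

    missing_share = out.groupby("area_id")["pm25"].apply(lambda s: s.isna().mean())
    for area_id, share in missing_share.items():
        if share > 0.5:
            warnings.warn(
                f"area {area_id}: no in-radius PM station for {share:.0%} of days",
                stacklevel=2,
            )
            logger.warning("area %s missing exposure on %.0f%% of days", area_id, 100 * share)
    return out
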