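"""Source attribution: counterfactual PM2.5 and WHS/LFS day labelling.

Each area's counterfactual (background) concentration is the mean of its
summer daily PM2.5 after removing likely fire days — summer days above the
95th percentile of the area's historical daily values. Days at or below
the counterfactual are unpolluted; the excess on other days is the
source-attributable PM2.5. Polluted winter days are labelled wood-heater
smoke (WHS) and polluted summer days landscape-fire smoke (LFS); polluted
days in the transition months (March, April, September, October) get their
label from a random forest trained on the season-labelled days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder

__all__ = [
    "SeasonScheme",
    "identify_fire_days",
    "compute_counterfactual",
    "counterfactual_table",
    "attribute_pm",
    "label_seasonal",
    "train_transition_classifier",
    "predict_transition_sources",
    "classify_days",
    "summarize_day_types",
]

DEFAULT_FIRE_PERCENTILE = 95.0
MIN_HISTORY_DAYS = 20

#: classifier feature set: location, calendar, exposure and weather.
#: month is categorical: its numeric ordering is meaningless across the
#: year boundary (Dec=12 borders Jan=1) and would place transition months
#: spuriously "next to" the summer training months.
NUMERIC_FEATURES = ["year", "day", "pm25", "hdd", "tmin", "tmax"]
CATEGORICAL_FEATURES = ["area_id", "month", "day_of_week"]


@dataclass(frozen=True)
class SeasonScheme:
    """Month partition into winter (WHS), summer (LFS) and transition months."""

    winter_months: frozenset = frozenset({5, 6, 7, 8})
    summer_months: frozenset = frozenset({11, 12, 1, 2})

    def __post_init__(self):
        if self.winter_months & self.summer_months:
            raise ValueError("winter and summer months overlap")
        if not (self.winter_months | self.summer_months) <= set(range(1, 13)):
            raise ValueError("months must be 1..12")

    @property
    def transition_months(self) -> frozenset:
        return frozenset(range(1, 13)) - self.winter_months - self.summer_months

    def season_of(self, months) -> np.ndarray:
        m = np.asarray(months)
        out = np.full(m.shape, "transition", dtype=object)
        out[np.isin(m, list(self.winter_months))] = "winter"
        out[np.isin(m, list(self.summer_months))] = "summer"
        return out


def identify_fire_days(
    area_series: pd.DataFrame,
    percentile: float = DEFAULT_FIRE_PERCENTILE,
    summer_months=frozenset({11, 12, 1, 2}),
    historical: str = "all",
) -> set:
    """Likely landscape-fire days for one area.

    Summer dates whose daily PM2.5 strictly exceeds the area's percentile
    threshold. The threshold is computed over all non-missing historical
    daily values (``historical='all'``, the default) or over summer values
    only (``historical='summer'``).
    """
    s = area_series.dropna(subset=["pm25"])
    if len(s) < MIN_HISTORY_DAYS:
        area = area_series["area_id"].iloc[0] if len(area_series) else "<empty>"
        raise ValueError(
            f"area {area}: only {len(s)} non-missing daily values; "
            f"need at least {MIN_HISTORY_DAYS} to set a fire-day threshold"
        )
    months = pd.to_datetime(s["date"]).dt.month
    is_summer = months.isin(list(summer_months))
    pool = s.loc[is_summer, "pm25"] if historical == "summer" else s["pm25"]
    threshold = np.percentile(pool.to_numpy(), percentile)  # linear interpolation
    fire = s.loc[is_summer & (s["pm25"] > threshold), "date"]
    return set(pd.to_datetime(fire))


def compute_counterfactual(
    area_series: pd.DataFrame,
    fire_days: set,
    summer_months=frozenset({11, 12, 1, 2}),
) -> float:
    """Mean summer daily PM2.5 with fire days excluded (the background level)."""
    s = area_series.dropna(subset=["pm25"]).copy()
    dates = pd.to_datetime(s["date"])
    is_summer = dates.dt.month.isin(list(summer_months))
    keep = is_summer & ~dates.isin(pd.DatetimeIndex(sorted(fire_days)))
    if not keep.any():
        area = area_series["area_id"].iloc[0] if len(area_series) else "<empty>"
        raise ValueError(f"area {area}: no valid summer non-fire days for counterfactual")
    return float(s.loc[keep, "pm25"].mean())


def counterfactual_table(
    area_days: pd.DataFrame,
    scheme: SeasonScheme = SeasonScheme(),
    percentile: float = DEFAULT_FIRE_PERCENTILE,
    historical: str = "all",
) -> pd.DataFrame:
    """Per-area counterfactual PM2.5 and the fire days used to derive it."""
    rows = []
    fire_by_area: dict[str, set] = {}
    for area_id, grp in area_days.groupby("area_id", sort=True):
        fire = identify_fire_days(grp, percentile, scheme.summer_months, historical)
        cf = compute_counterfactual(grp, fire, scheme.summer_months)
        fire_by_area[area_id] = fire
        rows.append({"area_id": area_id, "counterfactual": cf, "n_fire_days": len(fire)})
    table = pd.DataFrame(rows)
    table.attrs["fire_days"] = fire_by_area
    table.attrs["percentile"] = percentile
    return table


def attribute_pm(pm25: float, counterfactual: float) -> tuple[bool, float]:
    """(polluted?, attributable PM2.5) for one area-day.

    Days at or below the counterfactual are unpolluted with zero
    attributable concentration; the excess is attributable otherwise.
    """
    if not (np.isfinite(pm25) and np.isfinite(counterfactual)):
        raise ValueError("pm25 and counterfactual must both be present")
    if pm25 <= counterfactual:
        return False, 0.0
    return True, float(pm25 - counterfactual)


def label_seasonal(classified: pd.DataFrame, scheme: SeasonScheme) -> pd.DataFrame:
    """Rule-based labels: polluted winter -> WHS, polluted summer -> LFS.

    Polluted transition days keep ``day_type`` NaN pending prediction.
    Adds ``label_origin`` in {rule_unpolluted, rule_season, predicted}.
    """
    out = classified.copy()
    season = scheme.season_of(pd.to_datetime(out["date"]).dt.month.to_numpy())
    polluted = out["pm25_attributable"] > 0
    out["day_type"] = np.select(
        [~polluted, polluted & (season == "winter"), polluted & (season == "summer")],
        ["unpolluted", "WHS", "LFS"],
        default=None,
    )
    out["label_origin"] = np.where(
        ~polluted, "rule_unpolluted", np.where(season == "transition", "predicted", "rule_season")
    )
    return out


def _feature_frame(df: pd.DataFrame) -> pd.DataFrame:
    dates = pd.to_datetime(df["date"])
    return pd.DataFrame(
        {
            "area_id": df["area_id"].astype(str),
            "year": dates.dt.year,
            "month": dates.dt.month.astype(str),
            "day": dates.dt.day,
            "pm25": df["pm25"],
            "hdd": df["hdd"],
            "day_of_week": dates.dt.dayofweek.astype(str),
            "tmin": df["tmin"],
            "tmax": df["tmax"],
        }
    )


def train_transition_classifier(
    labeled: pd.DataFrame,
    seed: int = 0,
    n_estimators: int = 500,
    holdout_fraction: float = 0.2,
) -> tuple[Pipeline, float]:
    """Fit the WHS-vs-LFS random forest on rule-labelled polluted days.

    Features: statistical area, year, month, day of month, daily PM2.5,
    daily HDD, day of week, minimum and maximum temperature. Returns the
    fitted pipeline (refit on all labelled days) and its accuracy on a
    stratified 20% holdout.
    """
    labeled = labeled[labeled["day_type"].isin(["WHS", "LFS"])]
    classes = labeled["day_type"].unique()
    if len(classes) < 2:
        raise ValueError(
            f"need both WHS and LFS among labelled polluted days; got {sorted(classes)}"
        )
    missing = [c for c in ("pm25", "hdd", "tmin", "tmax") if labeled[c].isna().any()]
    if missing:
        raise ValueError(f"labelled days have missing features: {missing}")

    x = _feature_frame(labeled)
    y = labeled["day_type"].to_numpy()

    def make_pipeline() -> Pipeline:
        pre = ColumnTransformer(
            [("cat", OneHotEncoder(handle_unknown="ignore"), CATEGORICAL_FEATURES)],
            remainder="passthrough",
        )
        rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
        return Pipeline([("features", pre), ("rf", rf)])

    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    probe = make_pipeline().fit(x_tr, y_tr)
    accuracy = float((probe.predict(x_te) == y_te).mean())

    model = make_pipeline().fit(x, y)
    return model, accuracy


def predict_transition_sources(
    model: Pipeline, transition_days: pd.DataFrame
) -> pd.Series:
    """Predict WHS/LFS for polluted transition-month area-days.

    Exact 0.5 posteriors break toward WHS when the day has any heating
    demand (HDD > 0), toward LFS otherwise.
    """
    if len(transition_days) == 0:
        return pd.Series([], dtype=object, index=transition_days.index)
    missing = [
        c for c in ("pm25", "hdd", "tmin", "tmax") if transition_days[c].isna().any()
    ]
    if missing:
        raise ValueError(f"transition days have missing features: {missing}")
    x = _feature_frame(transition_days)
    proba = model.predict_proba(x)
    classes = list(model.classes_)
    p_whs = proba[:, classes.index("WHS")]
    hdd = transition_days["hdd"].to_numpy()
    labels = np.where(
        p_whs > 0.5,
        "WHS",
        np.where(p_whs < 0.5, "LFS", np.where(hdd > 0, "WHS", "LFS")),
    )
    return pd.Series(labels, index=transition_days.index)


def classify_days(
    area_days: pd.DataFrame,
    scheme: SeasonScheme = SeasonScheme(),
    percentile: float = DEFAULT_FIRE_PERCENTILE,
    seed: int = 0,
    n_estimators: int = 500,
    historical: str = "all",
) -> pd.DataFrame:
    """Full classification: counterfactual, attribution, labels, prediction.

    Area-days with missing exposure are dropped. Returns the area-day table
    with counterfactual, pm25_attributable, day_type and label_origin, plus
    the classifier holdout accuracy in ``DataFrame.attrs['holdout_accuracy']``.
    """
    days = area_days.dropna(subset=["pm25"]).copy()
    cf = counterfactual_table(days, scheme, percentile, historical)
    days = days.merge(cf[["area_id", "counterfactual"]], on="area_id", how="left")
    # tolerance guards float drift from interpolation when pm25 should equal
    # the counterfactual exactly; far below any physical concentration
    polluted = days["pm25"] - days["counterfactual"] > 1e-9
    days["pm25_attributable"] = np.where(polluted, days["pm25"] - days["counterfactual"], 0.0)

    days = label_seasonal(days, scheme)

    unlabeled = days["day_type"].isna()
    accuracy = float("nan")
    if unlabeled.any():
        model, accuracy = train_transition_classifier(
            days[days["label_origin"] == "rule_season"], seed=seed, n_estimators=n_estimators
        )
        days.loc[unlabeled, "day_type"] = predict_transition_sources(
            model, days.loc[unlabeled]
        )
    days["day_type"] = days["day_type"].astype(str)
    days.attrs["holdout_accuracy"] = accuracy
    # plain dict: DataFrame attrs must stay cheaply comparable
    days.attrs["counterfactuals"] = dict(zip(cf["area_id"], cf["counterfactual"]))
    days.attrs["n_fire_days"] = dict(zip(cf["area_id"], cf["n_fire_days"]))
    return days


def summarize_day_types(classified: pd.DataFrame) -> pd.DataFrame:
    """Per day-type summary: average days/year, share and PM2.5 statistics."""
    years = pd.to_datetime(classified["date"]).dt.year
    # days/year averaged over area-years, so the shares add up to a full year
    n_area_years = classified.assign(year=years).groupby(["area_id", "year"]).ngroups
    total = len(classified)
    rows = []
    for day_type, grp in classified.groupby("day_type", sort=True):
        rows.append(
            {
                "day_type": day_type,
                "avg_days_per_year": len(grp) / max(n_area_years, 1),
                "share_pct": 100.0 * len(grp) / total,
                "pm25_mean": grp["pm25"].mean(),
                "pm25_sd": grp["pm25"].std(),
                "pm25_max": grp["pm25"].max(),
            }
        )
    return pd.DataFrame(rows)
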