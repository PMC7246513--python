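"""Monetisation of attributable health impacts.

Premature deaths are valued at the Value of Statistical Life (VSL, default
AUD$ 4.2 million in 2014 dollars); hospital admissions with a
cost-of-illness approach — either the bundled per-case averages (default:
AUD$ 7193 cardiovascular, AUD$ 7280 respiratory, 2016 dollars, which
already combine direct health-care cost and lost productivity) or
explicitly as unit cost + length of stay x daily salary; asthma ED visits
at AUD$ 705 per case (2016 dollars). Everything is inflated to a common
target price year (default 2018) with caller-supplied factors, and
summarised as policy indicators: cost per source-day, per year, and — for
wood-heater smoke — per woodstove-year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CostModel",
    "inflate",
    "mortality_cost",
    "admission_cost",
    "ed_cost",
    "cost_impacts",
    "indicators",
]

OUTCOME_KIND = {
    "all_cause_mortality": "mortality",
    "cvd_admission": "cvd",
    "rsp_admission": "rsp",
    "asthma_ed": "ed",
}


@dataclass(frozen=True)
class CostModel:
    """Monetary parameters; amounts carry the price year noted."""

    vsl: float = 4.2e6  # AUD, 2014 prices
    vsl_year: int = 2014
    unit_cost_cvd: float = 7193.0  # AUD per admission, 2016 prices
    unit_cost_rsp: float = 7280.0  # AUD per admission, 2016 prices
    unit_cost_ed: float = 705.0  # AUD per ED visit, 2016 prices
    unit_cost_year: int = 2016
    mean_los_cvd: float = 5.0  # days, component mode only
    mean_los_rsp: float = 4.0
    daily_salary: float = 230.0  # AUD/day lost productivity, component mode only
    bundled: bool = True  # per-case averages already include lost salary
    inflation_factors: dict = field(
        default_factory=lambda: {2014: 1.0, 2016: 1.0, 2018: 1.0}
    )
    target_year: int = 2018
    n_woodstoves: int = 69_317
    study_years: float | None = None  # None: derive from the classified date span

    def __post_init__(self):
        for name in ("vsl", "unit_cost_cvd", "unit_cost_rsp", "unit_cost_ed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def inflate(amount: float, from_year: int, model: CostModel) -> float:
    """Adjust an amount from its price year to the model's target year."""
    try:
        factor = model.inflation_factors[from_year]
    except KeyError:
        raise KeyError(
            f"no inflation factor from price year {from_year} to {model.target_year}"
        ) from None
    return amount * factor


def mortality_cost(cases: float, model: CostModel) -> float:
    """VSL valuation of premature deaths, in target-year dollars."""
    if cases < 0:
        raise ValueError("cases must be nonnegative")
    return cases * inflate(model.vsl, model.vsl_year, model)


def admission_cost(cases: float, outcome: str, model: CostModel) -> float:
    """Cost-of-illness valuation of hospital admissions.

    Bundled mode multiplies by the per-case average directly; component
    mode adds lost salary over the mean length of stay to the unit cost.
    """
    if outcome not in ("cvd", "rsp"):
        raise ValueError(f"unknown admission outcome {outcome!r}")
    if cases < 0:
        raise ValueError("cases must be nonnegative")
    unit = model.unit_cost_cvd if outcome == "cvd" else model.unit_cost_rsp
    if not model.bundled:
        los = model.mean_los_cvd if outcome == "cvd" else model.mean_los_rsp
        unit = unit + los * model.daily_salary
    return cases * inflate(unit, model.unit_cost_year, model)


def ed_cost(cases: float, model: CostModel) -> float:
    """Direct health-care cost of asthma ED presentations."""
    if cases < 0:
        raise ValueError("cases must be nonnegative")
    return cases * inflate(model.unit_cost_ed, model.unit_cost_year, model)


def _cost_one(cases: float, outcome: str, model: CostModel) -> float:
    kind = OUTCOME_KIND[outcome]
    if kind == "mortality":
        return mortality_cost(cases, model)
    if kind in ("cvd", "rsp"):
        return admission_cost(cases, kind, model)
    return ed_cost(cases, model)


def cost_impacts(impacts: pd.DataFrame, model: CostModel) -> pd.DataFrame:
    """Monetise case counts per source x outcome with bound-wise CIs.

    ``impacts`` must carry outcome, source, cases, cases_lo, cases_hi;
    rows are summed within source x outcome before costing (unit costs are
    linear, so order does not matter). The valuation mode is recorded in
    ``DataFrame.attrs['mode']``.
    """
    grouped = impacts.groupby(["source", "outcome"], sort=True, as_index=False)[
        ["cases", "cases_lo", "cases_hi"]
    ].sum()
    out = grouped.copy()
    out["cost"] = [
        _cost_one(c, o, model) for c, o in zip(grouped["cases"], grouped["outcome"])
    ]
    out["cost_lo"] = [
        _cost_one(c, o, model) for c, o in zip(grouped["cases_lo"], grouped["outcome"])
    ]
    out["cost_hi"] = [
        _cost_one(c, o, model) for c, o in zip(grouped["cases_hi"], grouped["outcome"])
    ]
    out.attrs["mode"] = "bundled" if model.bundled else "component"
    return out


def count_source_days(classified: pd.DataFrame, how: str = "calendar") -> dict[str, int]:
    """Number of WHS/LFS days for per-day indicators.

    ``calendar``: a date counts once per source when ANY area carries the
    label that day (the default denominator). ``area_day``: every area-day
    counts.
    """
    polluted = classified[classified["day_type"].isin(["WHS", "LFS"])]
    if how == "calendar":
        counts = polluted.groupby("day_type")["date"].nunique()
    elif how == "area_day":
        counts = polluted.groupby("day_type").size()
    else:
        raise ValueError("how must be 'calendar' or 'area_day'")
    return {src: int(counts.get(src, 0)) for src in ("WHS", "LFS")}


def indicators(
    costs: pd.DataFrame,
    classified: pd.DataFrame | None,
    model: CostModel,
    source_day_counts: dict | None = None,
    study_years: float | None = None,
) -> pd.DataFrame:
    """Policy indicators per source: total, per source-day, per year, per woodstove-year.

    Day counts come from ``classified`` (calendar-day convention) unless
    supplied directly. The averaging period defaults to the classified date
    span in years. The per-woodstove indicator only applies to WHS.
    """
    if source_day_counts is None:
        if classified is None:
            raise ValueError("need classified days or explicit source_day_counts")
        source_day_counts = count_source_days(classified)
    if study_years is None:
        study_years = model.study_years
    if study_years is None:
        dates = pd.to_datetime(classified["date"])
        study_years = ((dates.max() - dates.min()).days + 1) / 365.25
    if study_years <= 0:
        raise ValueError("study period must be positive")

    totals = costs.groupby("source")[["cost", "cost_lo", "cost_hi"]].sum()
    rows = []
    for source in ("WHS", "LFS"):
        if source not in totals.index:
            continue
        total = float(totals.loc[source, "cost"])
        n_days = source_day_counts.get(source, 0)
        rows.append(
            {
                "source": source,
                "total_cost": total,
                "total_cost_lo": float(totals.loc[source, "cost_lo"]),
                "total_cost_hi": float(totals.loc[source, "cost_hi"]),
                "n_source_days": n_days,
                "cost_per_day": total / n_days if n_days > 0 else np.nan,
                "cost_per_year": total / study_years,
                "cost_per_woodstove_year": (
                    total / study_years / model.n_woodstoves if source == "WHS" else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
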