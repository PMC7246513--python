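"""Sensitivity analysis: rerun the pipeline over a scenario grid.

Scenarios vary the fire-day percentile threshold, the months defining
winter (and hence the transition months), and whether transition-month
days with predicted source labels are included. The classifier is
retrained per scenario (season definitions change its training labels)
with the same seed for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import attribution, costs
from .pipeline import PipelineResult, run_pipeline
from .synthetic import SyntheticWorld

__all__ = ["ScenarioConfig", "run_scenario", "scenario_grid", "DEFAULT_GRID"]

INDICATOR_COLUMNS = ["total_cost", "cost_per_day", "cost_per_year", "cost_per_woodstove_year"]

#: the default grid: every percentile and winter definition the study grid
#: spans, crossed with both treatments of predicted transition labels
DEFAULT_GRID = {
    "percentiles": (75.0, 90.0, 95.0, 99.0),
    "winter_defs": ((5, 6, 7, 8), (5, 6, 7), (6, 7)),
    "predicted_flags": (True, False),
}


@dataclass(frozen=True)
class ScenarioConfig:
    percentile: float = 95.0
    winter_months: frozenset = frozenset({5, 6, 7, 8})
    summer_months: frozenset = frozenset({11, 12, 1, 2})
    include_predicted: bool = True
    label: str = "main"

    def __post_init__(self):
        if not (50.0 < self.percentile < 100.0):
            raise ValueError("percentile must lie in (50, 100)")
        if self.winter_months & self.summer_months:
            raise ValueError("winter and summer months overlap")

    @property
    def scheme(self) -> attribution.SeasonScheme:
        return attribution.SeasonScheme(
            winter_months=frozenset(self.winter_months),
            summer_months=frozenset(self.summer_months),
        )


def run_scenario(
    scenario: ScenarioConfig,
    world: SyntheticWorld,
    seed: int = 0,
    cost_model: costs.CostModel = costs.CostModel(),
    n_estimators: int = 500,
    area_days: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, PipelineResult]:
    """One full pipeline run under a scenario; returns its indicator rows."""
    try:
        result = run_pipeline(
            world,
            scheme=scenario.scheme,
            percentile=scenario.percentile,
            seed=seed,
            cost_model=cost_model,
            include_predicted=scenario.include_predicted,
            n_estimators=n_estimators,
            area_days=area_days,
        )
    except Exception as exc:
        raise RuntimeError(f"scenario {scenario.label!r} failed: {exc}") from exc
    rows = result.indicators.copy()
    rows.insert(0, "label", scenario.label)
    rows.insert(1, "percentile", scenario.percentile)
    rows.insert(2, "winter_months", "-".join(map(str, sorted(scenario.winter_months))))
    rows.insert(3, "include_predicted", scenario.include_predicted)
    return rows, result


def scenario_grid(
    world: SyntheticWorld,
    percentiles=DEFAULT_GRID["percentiles"],
    winter_defs=DEFAULT_GRID["winter_defs"],
    predicted_flags=DEFAULT_GRID["predicted_flags"],
    summer_months=frozenset({11, 12, 1, 2}),
    seed: int = 0,
    cost_model: costs.CostModel = costs.CostModel(),
    n_estimators: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every scenario in the grid and summarise indicator ranges.

    Returns (per-scenario indicator table, range table with one row per
    source x include_predicted group giving the min/max of each indicator).
    The exposure surface is computed once and shared across scenarios.
    """
    if not (len(percentiles) and len(winter_defs) and len(predicted_flags)):
        raise ValueError("scenario grid must be nonempty")
    from .pipeline import area_days_from_world

    area_days = area_days_from_world(world)
    frames = []
    for include in predicted_flags:
        for pct in percentiles:
            for winter in winter_defs:
                label = f"p{pct:g}_w{'-'.join(map(str, winter))}_{'incl' if include else 'excl'}"
                cfg = ScenarioConfig(
                    percentile=pct,
                    winter_months=frozenset(winter),
                    summer_months=frozenset(summer_months),
                    include_predicted=include,
                    label=label,
                )
                rows, _ = run_scenario(
                    cfg, world, seed=seed, cost_model=cost_model,
                    n_estimators=n_estimators, area_days=area_days,
                )
                frames.append(rows)
    table = pd.concat(frames, ignore_index=True)

    ranges = (
        table.groupby(["include_predicted", "source"], sort=True)[INDICATOR_COLUMNS]
        .agg(["min", "max"])
    )
    ranges.columns = [f"{col}_{stat}" for col, stat in ranges.columns]
    return table, ranges.reset_index()
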