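import pandas as pd
import pytest
from hypothesis import settings

import smokeburden as sb

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> sb.GeneratorConfig:
    """Compact world: 6 areas, 2 full years, enough seasons for every module."""
    return sb.GeneratorConfig(
        n_areas=6,
        n_pm_stations=6,
        n_met_stations=6,
        start="2015-01-01",
        end="2016-12-31",
        seed=1,
    )


@pytest.fixture(scope="session")
def small_world(small_config) -> sb.SyntheticWorld:
    return sb.generate_world(small_config)


@pytest.fixture(scope="session")
def small_area_days(small_world) -> pd.DataFrame:
    return sb.area_days_from_world(small_world)


@pytest.fixture(scope="session")
def small_result(small_world, small_area_days) -> sb.PipelineResult:
    return sb.run_pipeline(
        small_world, seed=1, n_estimators=200, area_days=small_area_days
    )


@pytest.fixture(scope="session")
def truth_merged(small_world, small_result) -> pd.DataFrame:
    """Classified area-days joined to generator truth (suffix _true)."""
    cl = small_result.classified.copy()
    cl["date"] = pd.to_datetime(cl["date"])
    return cl.merge(small_world.truth, on=["area_id", "date"], suffixes=("", "_true"))
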