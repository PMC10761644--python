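"""Shared fixtures: a small, fast synthetic system built once per session."""

import dataclasses

import pandas as pd
import pytest

from compoundhaz import pipeline, synthetic


@pytest.fixture(scope="session")
def fast_config() -> synthetic.SyntheticConfig:
    """Reduced-years study conditions for quick unit tests."""
    return synthetic.SyntheticConfig(
        climatology_years=(2000, 2005), analysis_years=(2006, 2007), seed=11)


@pytest.fixture(scope="session")
def fast_system(fast_config):
    """(counties, temps, usdm, thresholds, events, episodes, calendar)."""
    counties = synthetic.make_counties(fast_config)
    temps = synthetic.simulate_temperature(counties, fast_config)
    usdm = synthetic.simulate_usdm(counties, fast_config)
    thresholds, events, episodes, calendar = pipeline.build_exposure(
        temps, usdm, fast_config)
    return counties, temps, usdm, thresholds, events, episodes, calendar


@pytest.fixture(scope="session")
def fast_visits(fast_config, fast_system):
    counties, _, _, _, _, _, calendar = fast_system
    return synthetic.simulate_visits(counties, calendar, fast_config)


def make_thresholds_frame(county_id: str, t90: float, t95: float):
    """Flat day-of-year thresholds for hand-traced detector tests."""
    return pd.DataFrame({"county_id": county_id, "doy": range(1, 366),
                         "t90": t90, "t95": t95})


def temps_frame(county_id: str, start: str, values):
    dates = pd.date_range(start, periods=len(values), freq="D")
    return pd.DataFrame({"county_id": county_id, "date": dates,
                         "tmean_c": values})
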