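"""Shared fixtures: all test data is generated programmatically."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from defaunation.simulate import ScenarioConfig, survey_scale_fixture


def make_stations(n=3, site="siteA", landscape="L1", spacing=2500.0,
                  start="2015-01-01", days=60):
    start = dt.date.fromisoformat(start)
    return pd.DataFrame({
        "station_id": [f"{site}_st{j + 1}" for j in range(n)],
        "site_id": site,
        "landscape_id": landscape,
        "x": 500_000.0 + spacing * np.arange(n),
        "y": 500_000.0 + np.zeros(n),
        "deploy_start": [start] * n,
        "deploy_end": [start + dt.timedelta(days=days - 1)] * n,
    })


def make_records(rows):
    """rows: iterable of (station_id, unit_id, iso_date)."""
    return pd.DataFrame(
        [(s, u, dt.date.fromisoformat(d)) for s, u, d in rows],
        columns=["station_id", "unit_id", "date"])


@pytest.fixture(scope="session")
def small_scenario():
    """One-landscape scenario small enough for second-scale MCMC."""
    return ScenarioConfig(
        landscapes=("degraded",), sites_per_landscape=2, stations_per_site=12,
        n_units=8, villages_per_landscape={"degraded": 5}, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    return survey_scale_fixture(seed=7, config=small_scenario)
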