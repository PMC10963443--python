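import datetime as dt

import numpy as np
import pandas as pd
import pytest

from microclim.types import SCHEDULE_HOURS, LoggerSeries
from microclim.synthetic import default_study_config, generate


def make_series(
    site_id="site",
    window=(dt.date(2022, 3, 1), dt.date(2023, 2, 28)),
    temp_fn=None,
    rh_fn=None,
):
    """Build a schedule-complete series from callables of (date, hour)."""
    temp_fn = temp_fn or (lambda d, h: 10.0)
    rh_fn = rh_fn or (lambda d, h: 60.0)
    rows = []
    d = window[0]
    while d <= window[1]:
        for h in SCHEDULE_HOURS:
            rows.append(
                (dt.datetime.combine(d, dt.time(h)), temp_fn(d, h), rh_fn(d, h))
            )
        d += dt.timedelta(days=1)
    return LoggerSeries.from_records(site_id, rows, window=window)


@pytest.fixture
def one_day_window():
    return (dt.date(2022, 3, 1), dt.date(2022, 3, 1))


@pytest.fixture(scope="session")
def default_network():
    """One generated default-study network, shared across tests (seed 7)."""
    cfg = default_study_config(seed=7)
    series, sites, truth = generate(cfg)
    return cfg, series, sites, truth


@pytest.fixture(scope="session")
def zero_noise_network():
    from dataclasses import replace

    cfg = replace(
        default_study_config(seed=3),
        noise_sd_t=0.0,
        noise_sd_rh=0.0,
        synoptic_sd=0.0,
        quantize=None,
    )
    series, sites, truth = generate(cfg)
    return cfg, series, sites, truth
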