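"""Daily/monthly aggregation and bioclimatic indices against enumeration oracles."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from microclim.aggregate import (
    bio7_continentality,
    bioclim_summary,
    daily_summaries,
    drt_day_matrix,
    monthly_means,
    network_bioclim,
)
from microclim.errors import IncompleteYearError, ValidationError
from microclim.types import SCHEDULE_HOURS, LoggerSeries, SiteMeta

from conftest import make_series

W_YEAR = (dt.date(2022, 3, 1), dt.date(2023, 2, 28))


def test_daily_summary_of_six_known_values(one_day_window):
    temps = dict(zip(SCHEDULE_HOURS, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
    s = make_series(window=one_day_window, temp_fn=lambda d, h: temps[h])
    out = daily_summaries(s)
    row = out.iloc[0]
    assert row.t_mean == 3.5 and row.t_min == 1 and row.t_max == 6 and row.drt == 5


def test_constant_day_has_zero_drt(one_day_window):
    s = make_series(window=one_day_window, temp_fn=lambda d, h: 10.0)
    assert daily_summaries(s).iloc[0].drt == 0.0


def test_sinusoidal_day_matches_enumeration(one_day_window):
    A = 4.2
    f = lambda d, h: 12.0 + A * np.cos(2 * np.pi * (h - 14) / 24)
    s = make_series(window=one_day_window, temp_fn=f)
    sampled = np.array([f(None, h) for h in SCHEDULE_HOURS])
    row = daily_summaries(s).iloc[0]
    assert row.drt == pytest.approx(sampled.max() - sampled.min())
    assert row.t_mean == pytest.approx(sampled.mean())


def test_partial_days_dropped_below_min_obs(one_day_window):
    s = make_series(window=one_day_window)
    partial = LoggerSeries("p", s.data.iloc[:4], window=s.window)
    assert daily_summaries(partial, min_obs=6).empty
    assert len(daily_summaries(partial, min_obs=4)) == 1


class TestMonthly:
    def test_identical_days(self):
        w = (dt.date(2022, 4, 1), dt.date(2022, 4, 30))
        out = monthly_means(daily_summaries(make_series(window=w, temp_fn=lambda d, h: 8.0)))
        assert len(out) == 1 and out.mmt.iloc[0] == 8.0 and out.n_days.iloc[0] == 30

    def test_two_months_kept_separate(self):
        w = (dt.date(2022, 4, 1), dt.date(2022, 5, 31))
        s = make_series(window=w, temp_fn=lambda d, h: 8.0 if d.month == 4 else 12.0)
        out = monthly_means(daily_summaries(s))
        assert list(out.mmt) == [8.0, 12.0]

    def test_february_ramp_mean(self):
        w = (dt.date(2023, 2, 1), dt.date(2023, 2, 28))
        s = make_series(window=w, temp_fn=lambda d, h: float(d.day))
        out = monthly_means(daily_summaries(s))
        assert out.mmt.iloc[0] == pytest.approx(14.5)  # mean of 1..28


class TestBio7:
    def _monthly(self, mmts):
        return pd.DataFrame(
            {
                "year": [2022] * len(mmts),
                "month": list(range(1, len(mmts) + 1)),
                "mmt": mmts,
                "n_days": [30] * len(mmts),
            }
        )

    def test_known_extremes(self):
        mmts = [16, 14, 11, 8, 5, 2, 3, 4, 6, 9, 12, 15]
        bio7, warm, cold = bio7_continentality(self._monthly(mmts))
        assert bio7 == 14 and warm == (2022, 1) and cold == (2022, 6)

    def test_all_equal_months_give_zero(self):
        bio7, warm, cold = bio7_continentality(self._monthly([5.0] * 12))
        assert bio7 == 0.0
        assert warm == cold == (2022, 1)  # earliest-month tie rule

    def test_sampled_annual_sinusoid_matches_monthly_averaging_oracle(self):
        A, phase = 7.0, 15
        f = lambda d, h: 9.0 + A * np.cos(2 * np.pi * (d.timetuple().tm_yday - phase) / 365)
        s = make_series(window=W_YEAR, temp_fn=f)
        bio7, warm, cold = bio7_continentality(monthly_means(daily_summaries(s)))
        # oracle: brute-force monthly means of the generating sinusoid
        days = pd.date_range(*W_YEAR, freq="D")
        vals = pd.Series(
            9.0 + A * np.cos(2 * np.pi * (days.dayofyear - phase) / 365), index=days
        )
        mmt = vals.groupby([days.year, days.month]).mean()
        assert bio7 == pytest.approx(mmt.max() - mmt.min(), abs=1e-9)
        assert warm[1] == 1 and cold[1] == 7

    def test_strict_mode_requires_twelve_months(self):
        with pytest.raises(IncompleteYearError):
            bio7_continentality(self._monthly([1.0, 2.0, 3.0]), strict=True)


class TestBioclimSummary:
    def test_constant_series(self):
        b = bioclim_summary(make_series(temp_fn=lambda d, h: 5.0))
        assert b.mat == 5.0 and b.bio7 == 0.0
        assert b.drt_annual == b.drt_wq == b.drt_cq == 0.0

    def test_warmest_quarter_has_90_days(self):
        s = make_series(temp_fn=lambda d, h: 14.0 if d.month in (12, 1, 2) else 2.0)
        b = bioclim_summary(s)
        # calendar oracle: Dec (31) + Jan (31) + Feb (28) of a non-leap window
        daily = daily_summaries(s)
        wq_days = pd.DatetimeIndex(daily.index).month.isin([12, 1, 2]).sum()
        assert wq_days == 90
        assert b.mdt_wq == pytest.approx(14.0) and b.mdt_cq == pytest.approx(2.0)

    def test_mat_conservation_against_monthly_means(self):
        rng = np.random.default_rng(0)
        temps = {}
        s = make_series(
            temp_fn=lambda d, h: temps.setdefault((d, h), float(rng.normal(8, 5)))
        )
        daily = daily_summaries(s)
        monthly = monthly_means(daily)
        mat = bioclim_summary(s).mat
        weighted = (monthly.mmt * monthly.n_days).sum() / monthly.n_days.sum()
        assert mat == pytest.approx(weighted, abs=1e-12)

    def test_shift_invariance_of_bio7_and_drt(self):
        f = lambda d, h: 6 * np.cos(2 * np.pi * (d.timetuple().tm_yday - 15) / 365) + h / 4
        a = bioclim_summary(make_series(temp_fn=f))
        b = bioclim_summary(make_series(temp_fn=lambda d, h: f(d, h) + 3.0))
        assert b.bio7 == pytest.approx(a.bio7, abs=1e-12)
        assert b.drt_annual == pytest.approx(a.drt_annual, abs=1e-12)
        assert b.mat == pytest.approx(a.mat + 3.0, abs=1e-12)

    def test_quarter_mdt_within_daily_range(self):
        rng = np.random.default_rng(1)
        temps = {}
        s = make_series(
            temp_fn=lambda d, h: temps.setdefault((d, h), float(rng.normal(5, 8)))
        )
        b = bioclim_summary(s)
        daily = daily_summaries(s)
        wq = pd.DatetimeIndex(daily.index).month.isin([12, 1, 2])
        assert daily.t_mean[wq].min() <= b.mdt_wq <= daily.t_mean[wq].max()


class TestDrtMatrix:
    def _meta(self, sid, sector=1, elev=500.0):
        return SiteMeta(sid, sector, "N", elev, "NotDomb", "stand")

    def test_identical_sites_have_identical_rows(self):
        f = lambda d, h: 10.0 + 3 * np.cos(2 * np.pi * (h - 14) / 24)
        net = [make_series(site_id="a", temp_fn=f), make_series(site_id="b", temp_fn=f)]
        sites = [self._meta("a"), self._meta("b", elev=600.0)]
        mat = drt_day_matrix(net, sites)
        assert (mat.loc["a"] == mat.loc["b"]).all()

    def test_larger_amplitude_dominates_everywhere(self):
        f1 = lambda d, h: 10.0 + 2 * np.cos(2 * np.pi * (h - 14) / 24)
        f2 = lambda d, h: 10.0 + 5 * np.cos(2 * np.pi * (h - 14) / 24)
        net = [make_series(site_id="lo", temp_fn=f1), make_series(site_id="hi", temp_fn=f2)]
        sites = [self._meta("lo"), self._meta("hi", elev=600.0)]
        mat = drt_day_matrix(net, sites)
        assert (mat.loc["hi"] > mat.loc["lo"]).all()

    def test_rows_sorted_by_sector_aspect_elevation(self):
        net = [make_series(site_id=s) for s in ("x", "y", "z")]
        sites = [
            SiteMeta("x", 2, "N", 700, "NotDomb", "stand"),
            SiteMeta("y", 1, "S", 900, "NotPumi", "stand"),
            SiteMeta("z", 1, "S", 600, "NotPumi", "stand"),
        ]
        mat = drt_day_matrix(net, sites)
        assert list(mat.index) == ["z", "y", "x"]

    def test_row_means_equal_annual_drt(self, default_network):
        _, series, sites, _ = default_network
        mat = drt_day_matrix(series[:5], sites)
        for s in series[:5]:
            b = bioclim_summary(s)
            assert mat.loc[s.site_id].mean() == pytest.approx(b.drt_annual)
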